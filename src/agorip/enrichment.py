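"""Between-library comparisons.

RIP-vs-IgG binding ratios per feature (TPM or RPKM treated as binding
density and compared directly, with a pseudocount for zeros) and the
replicate-level t-test used for proportion differences between genotypes.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def rip_vs_igg(
    values_a: Mapping[str, float],
    values_b: Mapping[str, float],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-feature log2 enrichment of condition A over condition B.

    ``log2((A + c) / (B + c))`` over the union of features; a feature absent
    from one table contributes 0 before the pseudocount. Antisymmetric under
    swapping the two conditions. The pseudocount is recorded in
    ``frame.attrs``.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    features = sorted(set(values_a) | set(values_b))
    a = np.array([float(values_a.get(f, 0.0)) for f in features])
    b = np.array([float(values_b.get(f, 0.0)) for f in features])
    frame = pd.DataFrame(
        {
            "feature": features,
            "value_a": a,
            "value_b": b,
            "log2_ratio": np.log2((a + pseudocount) / (b + pseudocount)),
        }
    )
    frame.attrs["pseudocount"] = pseudocount
    return frame


def proportion_ttest(
    fractions_group1: Sequence[float],
    fractions_group2: Sequence[float],
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-sample t-test on replicate-level fractions.

    Welch's unequal-variance form by default (Welch-Satterthwaite degrees
    of freedom); ``equal_var=True`` gives the pooled test. Needs at least
    two replicates per group to estimate a variance. Identical degenerate
    groups return (0, 1).
    """
    g1 = np.asarray(fractions_group1, dtype=float)
    g2 = np.asarray(fractions_group2, dtype=float)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need >= 2 replicates per group to estimate variance")
    if g1.std(ddof=1) == 0 and g2.std(ddof=1) == 0 and g1.mean() == g2.mean():
        return 0.0, 1.0
    t, p = stats.ttest_ind(g1, g2, equal_var=equal_var)
    return float(t), float(p)


def ttest_type1_rate(
    n_trials: int = 10_000,
    n_per_group: int = 2,
    alpha: float = 0.05,
    equal_var: bool = True,
    seed: int = 0,
) -> float:
    """Monte-Carlo type-I error rate of the two-sample t-test under a
    shared normal null.

    Both groups are drawn from the same distribution; the returned value is
    the fraction of trials with p < alpha. The pooled form (default here)
    is exact at the nominal level in this equal-variance design; the Welch
    form is conservative at very small n because its Satterthwaite degrees
    of freedom drop below the pooled value. Vectorized across trials.
    """
    rng = np.random.default_rng(seed)
    g1 = rng.normal(size=(n_per_group, n_trials))
    g2 = rng.normal(size=(n_per_group, n_trials))
    _, p = stats.ttest_ind(g1, g2, axis=0, equal_var=equal_var)
    return float(np.mean(p < alpha))


def log2_ratio(a: float, b: float, pseudocount: float = 1.0) -> float:
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return math.log2((a + pseudocount) / (b + pseudocount))
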