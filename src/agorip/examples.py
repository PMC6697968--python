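"""A small worked example library for the preprocessing cascade.

Twelve hand-constructed reads exercising every cleanup rule: N bases in the
insert and in the adapter region, full and partial (6-nt) 3' adapters, an
internal adapter occurrence, low-quality 3' tails, a fully low-quality read,
and inserts straddling the 16-nt length boundary. Used in the documentation
and as a pipeline self-check; the expected outcome of each read is stated in
line comments.
"""

from .io import Read
from .simulate import DEFAULT_ADAPTER

ADAPTER = DEFAULT_ADAPTER  # TGGAATTCTCGGGTGCCAAGG


def _read(rid, seq, qual=None):
    return Read(rid, seq, tuple(qual if qual is not None else [38] * len(seq)))


def twelve_read_library() -> list[Read]:
    insert21 = "TGGAATGTAAAGAAGTATGTA"
    insert20_no_t = "ACCAGACCAGACCAGACCAG"
    return [
        # r01: 21-nt insert + full adapter -> clipped to 21, survives
        _read("r01", insert21 + ADAPTER),
        # r02: N inside the insert -> dropped by the N filter
        _read("r02", "ACGTNACGTACGTACGTACGT" + ADAPTER),
        # r03: N in the adapter region -> dropped by the N filter (N anywhere)
        _read("r03", insert21 + ADAPTER[:10] + "N" + ADAPTER[11:]),
        # r04: 24-nt, no adapter, high quality -> survives unchanged
        _read("r04", "ACCAGACCAGACCAGACCAGACCA"),
        # r05: 20-nt insert + only the adapter's first 6 bases -> clipped to 20
        _read("r05", insert20_no_t + ADAPTER[:6]),
        # r06: 15-nt insert + adapter -> clipped to 15, dropped (< 16 nt)
        _read("r06", "ACCAGACCAGACCAG" + ADAPTER),
        # r07: 16-nt insert + adapter -> clipped to 16, survives (boundary)
        _read("r07", "ACCAGACCAGACCAGA" + ADAPTER),
        # r08: 30-nt, last 5 bases below Q20 -> trimmed to 25, survives
        _read("r08", "ACCAGACCAGACCAGACCAGACCAGACCAG", [38] * 25 + [10] * 5),
        # r09: all bases below Q20 -> trimmed to length 0, dropped
        _read("r09", "ACCAGACCAGACCAGACCAG", [5] * 20),
        # r10: 8-nt insert + partial adapter -> clipped to 8, dropped (< 16)
        _read("r10", "ACCAGACC" + ADAPTER[:10]),
        # r11: clean 21-nt read, no adapter -> survives unchanged
        _read("r11", "ACCAGACCAGACCAGACCAGA"),
        # r12: 19-nt insert (last 2 bases Q10) + adapter -> clip to 19,
        #      quality-trim to 17, survives
        _read("r12", "ACCAGACCAGACCAGACCA" + ADAPTER, [38] * 17 + [10] * 2 + [38] * 21),
    ]


#: reads expected to survive the full cascade, with their final lengths
EXPECTED_SURVIVORS = {
    "r01": 21,
    "r04": 24,
    "r05": 20,
    "r07": 16,
    "r08": 25,
    "r11": 21,
    "r12": 17,
}

#: expected FilterReport stage counts: (stage, reads in, reads out)
EXPECTED_REPORT = [
    ("n_filter", 12, 10),
    ("adapter_clip", 10, 10),
    ("quality_trim", 10, 10),
    ("length_filter", 10, 7),
]
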