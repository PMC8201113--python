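"""Independent brute-force recomputation of the Kano analysis.

Deliberately naive and self-contained: a literal 25-entry lookup, explicit
per-respondent loops and plain counters, sharing no code with the package.
Used to cross-check ``kanoqual.analyze`` cell-for-cell.
"""

from fractions import Fraction

LITERAL_TABLE = {
    (1, 1): "Q", (1, 2): "A", (1, 3): "A", (1, 4): "A", (1, 5): "O",
    (2, 1): "R", (2, 2): "I", (2, 3): "I", (2, 4): "I", (2, 5): "M",
    (3, 1): "R", (3, 2): "I", (3, 3): "I", (3, 4): "I", (3, 5): "M",
    (4, 1): "R", (4, 2): "I", (4, 3): "I", (4, 4): "I", (4, 5): "M",
    (5, 1): "R", (5, 2): "R", (5, 3): "R", (5, 4): "R", (5, 5): "Q",
}

TIE_ORDER = ["M", "O", "A", "I", "R", "Q"]


def brute_force_analyze(table):
    """attr_id -> (counts dict, classification letter, cs, ds) with exact
    rationals; cs/ds are None when A+O+M+I == 0."""
    out = {}
    for attribute in table.instrument.attributes:
        counts = {"A": 0, "Q": 0, "I": 0, "R": 0, "M": 0, "O": 0}
        for record in table.records:
            pair = record.answers.get(attribute.attr_id)
            if pair is None:
                continue
            letter = LITERAL_TABLE[(pair.functional, pair.dysfunctional)]
            counts[letter] = counts[letter] + 1
        if sum(counts.values()) == 0:
            continue
        best = None
        for letter in TIE_ORDER:
            if best is None or counts[letter] > counts[best]:
                best = letter
        den = counts["A"] + counts["O"] + counts["M"] + counts["I"]
        if den == 0:
            cs = ds = None
        else:
            cs = Fraction(counts["A"] + counts["O"], den)
            ds = -Fraction(counts["M"] + counts["O"], den)
        out[attribute.attr_id] = (counts, best, cs, ds)
    return out
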