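"""Independent oracles used by the tests.

These are deliberately naive, pure-Python re-derivations of the scoring
rules and thermodynamics — dict lookups and explicit loops, sharing no
code with the package — so agreement is meaningful.
"""

import math

POS5 = {1: 0.3, 2: 0.6, 3: 1.0}
POS3 = {0: 0.3, 1: 0.8, 2: 1.1}
BP = {("A", "C"): 1.2, ("T", "C"): 1.2, ("G", "U"): 0.7, ("T", "G"): 0.4}
RNA = {"A": "U", "C": "G", "G": "C", "T": "A"}


def position_weight(pos: int, length: int) -> float:
    if pos in POS5 and pos <= 3:
        w5 = POS5[pos]
    else:
        w5 = None
    from_3p = length - pos
    w3 = POS3.get(from_3p) if from_3p <= 2 else None
    if w5 is not None:
        return w5
    if w3 is not None:
        return w3
    return 1.2


def window_score(probe: str, window: str) -> tuple[int, float]:
    """(mismatch count, wMM) of a probe over one sense-strand window."""
    n, total = 0, 0.0
    for i, (pb, sb) in enumerate(zip(probe, window), start=1):
        if sb == "N" or pb != sb:
            n += 1
            rna = "N" if sb == "N" else RNA[sb]
            total += position_weight(i, len(probe)) * BP.get((pb, rna), 1.0)
    return n, total


def brute_best(probe: str, target: str, max_mm: int = 3):
    """Exhaustive window scan; returns (offset 1-based, wMM) or None."""
    best = None
    for off in range(len(target) - len(probe) + 1):
        n, w = window_score(probe, target[off : off + len(probe)])
        if n <= max_mm and (best is None or w < best[1] - 1e-12):
            best = (off + 1, w)
    return best


# --- nearest-neighbour Tm (unified DNA/DNA set, entropy salt correction)

_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT = {"A": (2.3, 4.1), "T": (2.3, 4.1), "G": (0.1, -2.8), "C": (0.1, -2.8)}


def nn_tm(seq: str, ct_nM: float = 250.0, na_mM: float = 50.0) -> float:
    """Duplex Tm (deg C) for a non-self-complementary oligo."""
    dh, ds = 0.0, 0.0
    for end in (seq[0], seq[-1]):
        h, s = _INIT[end]
        dh += h
        ds += s
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i : i + 2]]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    return 1000.0 * dh / (ds + 1.987 * math.log(ct_nM / 4.0 * 1e-9)) - 273.15
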