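"""Independent oracles used by the test-suite.

Each oracle recomputes a quantity the package computes, by a deliberately
different route (closed-form enumeration, naive per-read counting, exact
rational arithmetic), and is kept free of psiforge's implementation code
paths.
"""

from __future__ import annotations

import math
import re
from fractions import Fraction


def expected_psi_ratio(
    molecule_length: int,
    site_hazards: dict[int, float],
    position: int,
    background: float,
    mean_read_length: float,
) -> float:
    """Closed-form expected Ψ-ratio at ``position`` under the RT-stop model.

    cDNA 3′-starts are uniform on 1..L; the natural length is geometric with
    mean ``mean_read_length`` truncated at the molecule 5′ end; scanning from
    the 3′-start downward, each site position terminates with its hazard
    (f·e) and each non-site position with ``background``. The ratio is the
    expected number of reads starting at the position divided by the
    expected number covering it (the ratio of a high-coverage estimate).
    """
    L = molecule_length
    g = 1.0 / mean_read_length
    hazard = [0.0] * (L + 2)
    for q in range(1, L + 1):
        hazard[q] = site_hazards.get(q, background)
    p = position
    start_total = 0.0
    cover_total = 0.0
    surv = 1.0  # prod of (1 - hazard[r]) for r in p+1..t, built up as t grows
    for t in range(p, L + 1):
        if t > p:
            surv *= 1.0 - hazard[t]
        k = t - p + 1  # natural length needed to reach p
        p_len_ge = (1.0 - g) ** (k - 1)
        p_len_eq = g * p_len_ge
        cover_total += surv * p_len_ge
        if p == 1:
            start_total += surv * p_len_ge
        else:
            start_total += surv * (p_len_ge * hazard[p] + p_len_eq * (1.0 - hazard[p]))
    return start_total / cover_total


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def naive_sam_profile(sam_text: str) -> dict[str, dict[str, dict[int, int]]]:
    """Per-read enumeration of 5′-start and overlap counts from SAM text.

    Returns ``{molecule: {"starts": {pos: n}, "overlap": {pos: n}}}`` with
    1-based positions; skips headers, unmapped (flag 0x4) and reverse
    (flag 0x10) records. Deletions count as covered, insertions/clips/skips
    do not.
    """
    out: dict[str, dict[str, dict[int, int]]] = {}
    for line in sam_text.splitlines():
        if not line or line.startswith("@"):
            continue
        fields = line.split("\t")
        flag = int(fields[1])
        if flag & 0x4 or flag & 0x10:
            continue
        molecule, pos, cigar = fields[2], int(fields[3]), fields[5]
        mol = out.setdefault(molecule, {"starts": {}, "overlap": {}})
        mol["starts"][pos] = mol["starts"].get(pos, 0) + 1
        ref = pos
        for num, op in _CIGAR_RE.findall(cigar):
            num = int(num)
            if op in "M=XD":
                for q in range(ref, ref + num):
                    mol["overlap"][q] = mol["overlap"].get(q, 0) + 1
                ref += num
            elif op == "N":
                ref += num
    return out


def fisher_exact_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration.

    Exact rational arithmetic; sums P(k) over all tables with the observed
    margins whose probability does not exceed the observed table's.
    """
    n, r1, c1 = a + b + c + d, a + b, a + c
    if n == 0:
        return Fraction(1)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    denom = math.comb(n, c1)
    probs = {k: Fraction(math.comb(r1, k) * math.comb(n - r1, c1 - k), denom)
             for k in range(lo, hi + 1)}
    obs = probs[a]
    return min(Fraction(1), sum(pk for pk in probs.values() if pk <= obs))
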