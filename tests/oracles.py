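"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as directly as possible (quadratic scans,
explicit template tables, exact rational arithmetic) and deliberately
shares no code with the package internals it verifies.
"""

from fractions import Fraction
from math import comb

import numpy as np


def brute_force_overlap(a_df, b_df, min_overlap=1):
    """All-vs-all quadratic interval pairing on half-open coordinates."""
    pairs = []
    for i, ra in a_df.iterrows():
        for j, rb in b_df.iterrows():
            if ra["chrom"] != rb["chrom"]:
                continue
            inter = min(ra["end"], rb["end"]) - max(ra["start"], rb["start"])
            if inter >= min_overlap:
                pairs.append((i, j, inter))
    return sorted(pairs)


def template_label_oracle(mef, d, esc, tol):
    """Rule-table enumeration of the trajectory label.

    Builds the full set of ideal (mef, course, esc) templates and picks,
    among templates whose references match exactly, the one with the
    fewest course mismatches (first in table order on ties); more than
    ``tol`` mismatches means complex.
    """
    t = len(d)
    table = []  # (label, mef, course, esc) in tie-break priority order
    table.append(("static_open", True, tuple([True] * t), True))
    table.append(("static_closed", False, tuple([False] * t), False))
    for k in range(1, t + 2):
        course = tuple(i >= k - 1 for i in range(t))
        table.append((f"CO{k}", False, course, True))
    for k in range(1, t + 2):
        course = tuple(i < k - 1 for i in range(t))
        table.append((f"OC{k}", True, course, False))
    best_label, best_m = None, None
    for label, tm, course, te in table:
        if tm != bool(mef) or te != bool(esc):
            continue
        m = sum(1 for x, y in zip(d, course) if bool(x) != y)
        if best_m is None or m < best_m:
            best_label, best_m = label, m
    if best_m is None or best_m > tol:
        return "complex"
    return best_label


def expected_overlap_uniform(setA_df, setB_df, chrom_lengths):
    """Closed-form E[#A regions overlapping B] under uniform relocation.

    For an A region of length L on a chromosome of length C, the start is
    uniform on [0, C-L]; it overlaps the (merged) B intervals iff the
    start falls in the union of [s-L+1, e-1] windows clipped to the valid
    range.
    """
    merged = {}
    for chrom, grp in setB_df.groupby("chrom"):
        ivs = sorted(zip(grp["start"], grp["end"]))
        out = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged[chrom] = out
    expected = 0.0
    for _, row in setA_df.iterrows():
        length = row["end"] - row["start"]
        c = chrom_lengths[row["chrom"]]
        windows = []
        for s, e in merged.get(row["chrom"], []):
            lo = max(0, s - length + 1)
            hi = min(c - length, e - 1)
            if hi >= lo:
                windows.append((lo, hi))
        windows.sort()
        union = 0
        cur = None
        for lo, hi in windows:
            if cur is None or lo > cur[1] + 1:
                if cur is not None:
                    union += cur[1] - cur[0] + 1
                cur = [lo, hi]
            else:
                cur[1] = max(cur[1], hi)
        if cur is not None:
            union += cur[1] - cur[0] + 1
        expected += union / (c - length + 1)
    return expected


def hypergeom_right_tail(k_t, n_t, k_b, n_b):
    """Exact hypergeometric right-tail P(X >= k_t) by rational summation."""
    N = n_t + n_b
    K = k_t + k_b
    denom = comb(N, n_t)
    total = Fraction(0)
    for i in range(k_t, min(K, n_t) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n_t - i), denom)
    return total


def brute_force_associate(regions_df, genes, upstream=5000, downstream=2000,
                          distal=100_000, promoter_hw=2000):
    """Per-base distance check of the region-gene rule, one pair at a time."""
    pairs = set()
    for i, row in regions_df.iterrows():
        bases = (row["start"], row["end"] - 1)  # first and last covered base
        for g in genes:
            if g.chrom != row["chrom"]:
                continue
            if g.strand == "+":
                dists = (bases[0] - g.tss, bases[1] - g.tss)
            else:
                dists = (g.tss - bases[1], g.tss - bases[0])
            lo, hi = min(dists), max(dists)

            def hits(a, b):
                return lo <= b and hi >= a

            if not hits(-distal, distal):
                continue
            if hits(-promoter_hw, promoter_hw):
                rel = "promoter_overlap"
            elif hits(-upstream, -1):
                rel = "upstream"
            elif hits(0, downstream):
                rel = "downstream"
            else:
                rel = "distal"
            pairs.add((i, g.gene_id, rel))
    return pairs


def pwm_rescan(seq, pwm, threshold):
    """Naive per-position rescan of both strands; returns hit offsets."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = pwm.shape[1]
    logodds = np.log2(np.clip(pwm, 1e-9, None) / 0.25)
    hits = []
    seq = seq.upper()
    rc = "".join(comp.get(c, "N") for c in reversed(seq))
    for strand, s in (("+", seq), ("-", rc)):
        for i in range(len(s) - L + 1):
            kmer = s[i : i + L]
            if any(c not in idx for c in kmer):
                continue
            score = sum(logodds[idx[c], j] for j, c in enumerate(kmer))
            if score >= threshold:
                fwd = i if strand == "+" else len(s) - L - i
                hits.append((fwd, strand))
    return sorted(hits)
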