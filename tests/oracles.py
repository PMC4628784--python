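"""Independent brute-force reference implementations used as test oracles.

Every function here is deliberately naive (exhaustive scans, per-base sets,
full enumeration) and shares no code with the library paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

STOPS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# ORF

def orf_brute(seq: str) -> int:
    """Longest ATG..stop ORF by scanning every (frame, start, stop) triple."""
    seq = seq.upper()
    best = 0
    for start in range(len(seq) - 2):
        if seq[start:start + 3] != "ATG":
            continue
        for stop in range(start + 3, len(seq) - 2, 3):
            codon = seq[stop:stop + 3]
            if codon in STOPS:
                best = max(best, stop + 3 - start)
                break
    return best


# ---------------------------------------------------------------------------
# Fickett TESTCODE (straight-line re-implementation of the lookup tables)

def fickett_brute(seq: str) -> float:
    seq = seq.upper()
    pos = {b: [0, 0, 0] for b in "ACGT"}
    for i, b in enumerate(seq):
        if b in pos:
            pos[b][i % 3] += 1
    total = sum(sum(v) for v in pos.values())
    score = 0.0
    tables = {
        "A": ([0.51, 0.55, 0.57, 0.52, 0.48, 0.58, 0.57, 0.54, 0.50, 0.36], 0.22,
              [0.40, 0.55, 0.58, 0.58, 0.52, 0.48, 0.45, 0.45, 0.38, 0.19], 0.11),
        "C": ([0.29, 0.44, 0.55, 0.49, 0.49, 0.37, 0.38, 0.30, 0.23, 0.20], 0.23,
              [0.50, 0.63, 0.59, 0.50, 0.41, 0.30, 0.33, 0.29, 0.24, 0.18], 0.12),
        "G": ([0.62, 0.67, 0.74, 0.65, 0.61, 0.62, 0.52, 0.41, 0.31, 0.17], 0.24,
              [0.21, 0.40, 0.47, 0.46, 0.52, 0.58, 0.57, 0.52, 0.44, 0.11], 0.15),
        "T": ([0.51, 0.60, 0.69, 0.64, 0.53, 0.54, 0.44, 0.40, 0.31, 0.33], 0.18,
              [0.30, 0.49, 0.56, 0.53, 0.48, 0.48, 0.34, 0.20, 0.11, 0.33], 0.14),
    }
    for b in "ACGT":
        pp, pw, cp, cw = tables[b]
        counts = pos[b]
        value = max(counts) / (min(counts) + 1.0)
        if value >= 1.9:
            p = pp[0]
        elif value >= 1.8:
            p = pp[1]
        elif value >= 1.7:
            p = pp[2]
        elif value >= 1.6:
            p = pp[3]
        elif value >= 1.5:
            p = pp[4]
        elif value >= 1.4:
            p = pp[5]
        elif value >= 1.3:
            p = pp[6]
        elif value >= 1.2:
            p = pp[7]
        elif value >= 1.1:
            p = pp[8]
        else:
            p = pp[9]
        score += p * pw
        frac = sum(counts) / total if total else 0.0
        if frac >= 0.33:
            c = cp[0]
        elif frac >= 0.31:
            c = cp[1]
        elif frac >= 0.29:
            c = cp[2]
        elif frac >= 0.27:
            c = cp[3]
        elif frac >= 0.25:
            c = cp[4]
        elif frac >= 0.23:
            c = cp[5]
        elif frac >= 0.21:
            c = cp[6]
        elif frac >= 0.19:
            c = cp[7]
        elif frac >= 0.17:
            c = cp[8]
        else:
            c = cp[9]
        score += c * cw
    return score


# ---------------------------------------------------------------------------
# Folding: exhaustive enumeration over all nested pairings

_PAIR_E = {frozenset("GC"): -3.0, frozenset(("A", "U")): -2.0, frozenset("GU"): -1.0}


def _pair_energy(a: str, b: str):
    return _PAIR_E.get(frozenset((a, b)))


def fold_enumerate(seq: str, min_loop: int = 3) -> float:
    """Minimum energy over all nested pairings by plain recursion (no memo)."""
    seq = seq.upper().replace("T", "U")

    def best(i: int, j: int) -> float:
        if i >= j:
            return 0.0
        value = best(i + 1, j)  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            e = _pair_energy(seq[i], seq[k])
            if e is None:
                continue
            value = min(value, e + best(i + 1, k - 1) + best(k + 1, j))
        return value

    return best(0, len(seq) - 1)


# ---------------------------------------------------------------------------
# Interval overlap / locus grouping / TE coverage

def overlap_brute(set_a, set_b, min_bp: int = 1):
    pairs = []
    for i, a in enumerate(set_a):
        for j, b in enumerate(set_b):
            if a.chrom != b.chrom:
                continue
            ov = min(a.end, b.end) - max(a.start, b.start)
            if ov >= min_bp:
                pairs.append((i, j, ov))
    return pairs


def loci_brute(transcripts):
    """Single-linkage grouping over all transcript pairs (exonic overlap)."""
    n = len(transcripts)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    def overlap(a, b):
        if a.chrom != b.chrom or a.strand != b.strand:
            return False
        for ea in a.exons:
            for eb in b.exons:
                if min(ea.end, eb.end) - max(ea.start, eb.start) >= 1:
                    return True
        return False

    for i in range(n):
        for j in range(i + 1, n):
            if overlap(transcripts[i], transcripts[j]):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups = {}
    for i, tx in enumerate(transcripts):
        groups.setdefault(find(i), set()).add(tx.transcript_id)
    return {frozenset(g) for g in groups.values()}


def te_covered_brute(transcript, te_elements) -> int:
    """Per-base TE coverage of the transcript's exons via position sets."""
    covered = set()
    for te in te_elements:
        if te.chrom != transcript.chrom:
            continue
        covered.update(range(te.start, te.end))
    return sum(1 for e in transcript.exons for p in range(e.start, e.end) if p in covered)


# ---------------------------------------------------------------------------
# Hotspots

def hotspot_brute(positions, window: int = 100, min_count: int = 6):
    """Naive window enumeration: every qualifying 1-bp-slid window, merged
    when strictly overlapping; returns [(start, end, max_count), ...]."""
    positions = sorted(positions)
    if not positions:
        return []
    qualifying = []
    for s in range(max(0, positions[0] - window + 1), positions[-1] + 1):
        count = sum(1 for p in positions if s <= p < s + window)
        if count >= min_count:
            qualifying.append((s, s + window, count))
    if not qualifying:
        return []
    merged = [[qualifying[0][0], qualifying[0][1], qualifying[0][2]]]
    for s, e, c in qualifying[1:]:
        if s < merged[-1][1]:
            merged[-1][1] = e
            merged[-1][2] = max(merged[-1][2], c)
        else:
            merged.append([s, e, c])
    return [tuple(m) for m in merged]


# ---------------------------------------------------------------------------
# Exact small-sample statistics

def hypergeom_enumerate(universe: int, size_a: int, size_b: int, overlap: int) -> float:
    """P(|A ∩ B| >= overlap) by enumerating every B-draw of the universe."""
    items = list(range(universe))
    a = set(items[:size_a])
    total = 0
    hits = 0
    for draw in itertools.combinations(items, size_b):
        total += 1
        if len(a & set(draw)) >= overlap:
            hits += 1
    return hits / total


def ranksum_enumerate(x, y) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all group labelings."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_stat(first_idx):
        first = [pooled[i] for i in first_idx]
        rest = [pooled[i] for i in range(len(pooled)) if i not in set(first_idx)]
        u = 0.0
        for a in first:
            for b in rest:
                if a > b:
                    u += 1.0
                elif a == b:
                    u += 0.5
        return u

    observed = 0.0
    for a in x:
        for b in y:
            if a > b:
                observed += 1.0
            elif a == b:
                observed += 0.5
    us = [u_stat(idx) for idx in itertools.combinations(range(len(pooled)), n1)]
    us = np.array(us)
    p_ge = np.mean(us >= observed)
    p_le = np.mean(us <= observed)
    return min(1.0, 2 * min(p_ge, p_le))


def welch_t_brute(a, b):
    """Hand-computed Welch t statistic and dof."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    dof = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    return t, dof
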