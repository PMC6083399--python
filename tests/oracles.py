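"""Independent brute-force oracles the implementation is checked against.

These are written for clarity, not speed: exhaustive python loops with no
shared code with the package internals.
"""

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq):
    return "".join(_COMP.get(b, "N") for b in reversed(seq.upper()))


def _scan_all(seq, pat, max_mm, anchor_len, anchor_at_start):
    """Every offset where pat matches seq (exhaustive sliding window).

    A position matches when the characters are equal and both are plain
    bases (genomic N or primer N never match).  Anchored positions must
    match exactly.
    """
    m = len(pat)
    out = {}
    for i in range(len(seq) - m + 1):
        mm = 0
        anchor_ok = True
        for t in range(m):
            g, p = seq[i + t], pat[t]
            match = g == p and p in "ACGT" and g in "ACGT"
            if not match:
                mm += 1
                in_anchor = t < anchor_len if anchor_at_start else t >= m - anchor_len
                if in_anchor:
                    anchor_ok = False
        if anchor_ok and mm <= max_mm:
            out[i] = mm
    return out


def naive_primer_hits(genome, fwd, rev, max_mm, anchor, bounds):
    """All amplifiable loci as (chrom, start, end, orientation, fwd_mm, rev_mm).

    Tries both product orientations; the left primer is anchored at its 3'
    (last) bases, the right pattern — a reverse complement — at its first.
    """
    lo, hi = bounds
    hits = []
    for chrom in genome:
        seq = genome[chrom].upper()
        for left, right, orient in ((fwd, rc(rev), "plus"), (rev, rc(fwd), "minus")):
            left_sites = _scan_all(seq, left.upper(), max_mm, anchor, False)
            right_sites = _scan_all(seq, right.upper(), max_mm, anchor, True)
            for i, lmm in left_sites.items():
                for j, rmm in right_sites.items():
                    end = j + len(right)
                    if lo <= end - i <= hi:
                        f, v = (lmm, rmm) if orient == "plus" else (rmm, lmm)
                        hits.append((chrom, i, end, orient, f, v))
    return sorted(hits)


def oracle_overlap_components(intervals):
    """Connected components of the same-stratum interval-overlap graph by
    all-pairs union-find; returns the member-id sets of components with
    >= 2 members from >= 2 distinct (population, source) signals."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = intervals[i], intervals[j]
            if a.chrom != b.chrom or a.trait != b.trait:
                continue
            if a.start < b.end and b.start < a.end:
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(intervals[i])
    out = set()
    for members in comps.values():
        if len(members) < 2:
            continue
        signals = {(iv.qtl.population, iv.qtl.source) for iv in members}
        if len(signals) < 2:
            continue
        out.add(frozenset(iv.qtl_id for iv in members))
    return out


def oracle_degrees(nodes, edge_pairs):
    """Node degrees as adjacency-matrix row sums, built by hand."""
    idx = {n: i for i, n in enumerate(nodes)}
    size = len(nodes)
    matrix = [[0] * size for _ in range(size)]
    for a, b in edge_pairs:
        i, j = idx[a], idx[b]
        matrix[i][j] = 1
        matrix[j][i] = 1
    return {n: sum(matrix[idx[n]]) for n in nodes}
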