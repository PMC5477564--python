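"""Independent oracle implementations used by the test suite.

These deliberately avoid the package's indexed/vectorised code paths: the
extension oracles apply the collision rules by direct all-pairs scanning or
base-by-base walking, the Ward oracle runs the naive O(n^3) greedy
Lance-Williams recursion, and the read-assignment oracle loops over every
gene for every read.
"""

from __future__ import annotations

import numpy as np


def pairwise_extension_oracle(gene, genes, chrom_lengths, max_ext):
    """All-pairs cap computation over the raw rule list.

    ``gene``/``genes`` are GeneModel objects taken at original coordinates;
    returns the oracle's new TTS for ``gene``.
    """
    others = [o for o in genes if o.gene_id != gene.gene_id and o.chrom == gene.chrom]
    chrom_len = chrom_lengths[gene.chrom]
    if gene.strand == "+":
        t = gene.end
        limit = min(t + max_ext, chrom_len)
        caps = [limit]
        for o in others:
            if o.end < t + 1 or o.start > limit:
                continue
            if o.strand == "+":
                caps.append(max(o.start - 1, t))
            elif t + 1 <= o.start <= limit:  # minus-strand TTS inside window
                caps.append((t + o.start) // 2)
            else:
                caps.append(max(o.start - 1, t))
        return max(min(caps), t)
    else:
        t = gene.start
        limit = max(t - max_ext, 1)
        caps = [limit]
        for o in others:
            if o.start > t - 1 or o.end < limit:
                continue
            if o.strand == "-":
                caps.append(min(o.end + 1, t))
            elif limit <= o.end <= t - 1:  # plus-strand TTS inside window
                caps.append((t + o.end) // 2 + 1)
            else:
                caps.append(min(o.end + 1, t))
        return min(max(caps), t)


def walk_extension_oracle(gene, genes, chrom_lengths, max_ext):
    """Base-by-base walk 3' of the TTS; stops at the first forbidden base.

    A candidate base is forbidden when it falls inside any other gene body,
    or past the TTS midpoint of a convergent opposite-strand gene whose TTS
    lies in the window. Slow; use only on small instances.
    """
    others = [o for o in genes if o.gene_id != gene.gene_id and o.chrom == gene.chrom]
    chrom_len = chrom_lengths[gene.chrom]
    sign = 1 if gene.strand == "+" else -1
    t = gene.end if gene.strand == "+" else gene.start
    window_far = t + sign * max_ext

    def forbidden(pos):
        if pos < 1 or pos > chrom_len:
            return True
        for o in others:
            if o.start <= pos <= o.end:
                return True
            if o.strand != gene.strand:
                o_tts = o.start if o.strand == "-" else o.end
                in_window = (min(t + sign, window_far) <= o_tts <= max(t + sign, window_far))
                if in_window:
                    if gene.strand == "+" and pos > (t + o_tts) // 2:
                        return True
                    if gene.strand == "-" and pos < (t + o_tts) // 2 + 1:
                        return True
        return False

    new_tts = t
    for step in range(1, max_ext + 1):
        pos = t + sign * step
        if forbidden(pos):
            break
        new_tts = pos
    return new_tts


def naive_ward_d2_heights(dm: np.ndarray) -> np.ndarray:
    """Greedy ward.D2: Lance-Williams on squared distances, O(n^3).

    Ties broken on the lexicographically smallest cluster-id pair. Returns
    the sorted merge heights.
    """
    n = dm.shape[0]
    d2 = {(i, j): dm[i, j] ** 2 for i in range(n) for j in range(i + 1, n)}
    sizes = {i: 1 for i in range(n)}
    ids = list(range(n))
    heights = []
    next_id = n
    while len(ids) > 1:
        best = min(
            ((d2[(a, b)], a, b) for i, a in enumerate(ids) for b in ids[i + 1:]),
        )
        cost, a, b = best
        heights.append(np.sqrt(cost))
        na, nb = sizes[a], sizes[b]
        new = next_id
        next_id += 1
        for k in ids:
            if k in (a, b):
                continue
            nk = sizes[k]
            dak = d2[tuple(sorted((a, k)))]
            dbk = d2[tuple(sorted((b, k)))]
            d2[(k, new)] = ((na + nk) * dak + (nb + nk) * dbk - nk * cost) / (na + nb + nk)
        sizes[new] = na + nb
        ids = [k for k in ids if k not in (a, b)] + [new]
    return np.sort(np.array(heights))


def brute_force_assign(read, genes, spike_prefix="ERCC-"):
    """Loop every gene; overlap = >=1 bp intersection with any exon, same strand."""
    if read.chrom.startswith(spike_prefix):
        return "SPIKE_IN"
    hits = []
    for g in genes:
        if g.chrom != read.chrom or g.strand != read.strand:
            continue
        for s, e in g.exons:
            if s <= read.end and e >= read.start:
                hits.append(g.gene_id)
                break
    if not hits:
        return "UNASSIGNED"
    if len(hits) > 1:
        return "AMBIGUOUS"
    return hits[0]


def sort_percentile(values, q):
    """Linear-interpolation percentile computed from first principles."""
    xs = sorted(values)
    if len(xs) == 1:
        return xs[0]
    rank = q / 100 * (len(xs) - 1)
    lo = int(np.floor(rank))
    hi = int(np.ceil(rank))
    frac = rank - lo
    return xs[lo] * (1 - frac) + xs[hi] * frac


def random_annotation(rng, n_genes, chrom_len=300_000, chroms=("chr1",)):
    """Dense random gene set (overlaps allowed) for extension property tests."""
    from sc3kit.annotation import AnnotationSet, GeneModel, GenomeLayout

    biotypes = ["protein_coding"] * 6 + ["pseudogene", "tRNA", "ncRNA", "other"]
    genes = []
    for i in range(n_genes):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(1, chrom_len - 5_000))
        length = int(rng.integers(100, 5_000))
        end = min(start + length - 1, chrom_len)
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = biotypes[int(rng.integers(len(biotypes)))]
        genes.append(GeneModel(f"g{i:04d}", f"g{i:04d}", chrom, strand,
                               start, end, biotype=biotype))
    layout = GenomeLayout({c: chrom_len for c in chroms})
    return AnnotationSet(layout, genes)
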