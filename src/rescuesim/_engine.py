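"""Bit-level numba kernels for the population engine.

Genotypes are stored as bitsets: one ``uint64`` row of ``W`` words per
haplotype (two consecutive rows per diploid individual), one bit per
segregating site.  Sites are kept sorted by genomic position, so a gamete's
parental-haplotype chooser is piecewise constant over contiguous bit ranges
(no recombination within genes, rare switches between adjacent genes, free
recombination between chromosomes) and can be painted as word-range fills.

All kernels are pure functions of their inputs: every random number is drawn
from numpy Generators outside and passed in, which keeps replicate-level
determinism independent of compilation details.
"""

from __future__ import annotations

import numba as nb
import numpy as np

_DEBRUIJN = np.uint64(0x03F79D71B4CB0A89)
_DB_TABLE = np.zeros(64, dtype=np.int64)
for _i in range(64):
    _DB_TABLE[(((1 << _i) * 0x03F79D71B4CB0A89) & 0xFFFFFFFFFFFFFFFF) >> 58] = _i


@nb.njit(cache=True, inline="always")
def _fill_range(mask, a, b):
    """Set bits [a, b) in the word array ``mask``."""
    if a >= b:
        return
    one = np.uint64(1)
    full = ~np.uint64(0)
    wa = a >> 6
    wb = (b - 1) >> 6
    la = np.uint64(a & 63)
    lb = np.uint64(((b - 1) & 63) + 1)
    if wa == wb:
        width = lb - la
        if width == 64:
            mask[wa] = full
        else:
            mask[wa] |= ((one << width) - one) << la
    else:
        mask[wa] |= full << la
        for w in range(wa + 1, wb):
            mask[w] = full
        if lb == 64:
            mask[wb] = full
        else:
            mask[wb] |= (one << lb) - one


def build_span_table(chrom_first_site: np.ndarray, n_words: int):
    """CSR table mapping each genotype word to the chromosomes overlapping
    it: for word w, entries [ptr[w], ptr[w+1]) give (chromosome, bitmask of
    that chromosome's sites within the word).  Lets the crossover-free
    gamete path assemble its chooser mask with a couple of OR operations
    per word."""
    ptr = np.zeros(n_words + 1, dtype=np.int64)
    chroms, masks = [], []
    full = (1 << 64) - 1
    per_word = [[] for _ in range(n_words)]
    nc = len(chrom_first_site) - 1
    for c in range(nc):
        a, b = int(chrom_first_site[c]), int(chrom_first_site[c + 1])
        if a >= b:
            continue
        for w in range(a >> 6, ((b - 1) >> 6) + 1):
            lo = max(a, w << 6) - (w << 6)
            hi = min(b, (w + 1) << 6) - (w << 6)
            mask = ((full >> (64 - (hi - lo))) << lo) & full
            per_word[w].append((c, mask))
    for w in range(n_words):
        ptr[w + 1] = ptr[w] + len(per_word[w])
        for c, m in per_word[w]:
            chroms.append(c)
            masks.append(m)
    return (ptr, np.array(chroms, dtype=np.int64),
            np.array(masks, dtype=np.uint64))


@nb.njit(cache=True)
def make_gametes(geno, parent_idx, start_bits, k_cross, cross_u, cross_off,
                 adj_to_gene, chrom_first_gene, gene_first_site,
                 span_ptr, span_chrom, span_mask, out):
    """Build one gamete per entry of ``parent_idx`` into ``out``.

    ``start_bits[j]`` supplies one starting-haplotype bit per chromosome for
    gamete ``j`` (bit c = chromosome c).  ``k_cross[j]`` crossovers are
    placed at distinct adjacencies chosen via the uniforms in
    ``cross_u[cross_off[j]:cross_off[j+1]]`` (linear probing resolves the
    rare duplicate).  A crossover at adjacency a toggles the chooser before
    gene ``adj_to_gene[a]``.
    """
    n_gam = parent_idx.shape[0]
    W = out.shape[1]
    A = adj_to_gene.shape[0]
    nc = chrom_first_gene.shape[0] - 1
    kmax = 0
    for j in range(n_gam):
        if k_cross[j] > kmax:
            kmax = k_cross[j]
    adj_buf = np.empty(max(kmax, 1), dtype=np.int64)
    gene_buf = np.empty(max(kmax, 1), dtype=np.int64)
    mask = np.empty(W, dtype=np.uint64)
    one = np.uint64(1)
    for j in range(n_gam):
        k = k_cross[j]
        off = cross_off[j]
        if k == 0:
            # crossover-free: the chooser is constant per chromosome
            p0 = parent_idx[j]
            ra = 2 * p0
            rb = ra + 1
            sb0 = start_bits[j]
            for w in range(W):
                m = np.uint64(0)
                for e in range(span_ptr[w], span_ptr[w + 1]):
                    if (sb0 >> np.uint64(span_chrom[e])) & one:
                        m |= span_mask[e]
                out[j, w] = (geno[ra, w] & ~m) | (geno[rb, w] & m)
            continue
        for t in range(k):
            a = np.int64(cross_u[off + t] * A)
            if a >= A:
                a = A - 1
            probing = True
            while probing:
                probing = False
                for q in range(t):
                    if adj_buf[q] == a:
                        a = (a + 1) % A
                        probing = True
                        break
            adj_buf[t] = a
        for t in range(k):
            gene_buf[t] = adj_to_gene[adj_buf[t]]
        # insertion sort (k is almost always 0-2, ~20 for the full genome)
        for t in range(1, k):
            v = gene_buf[t]
            q = t - 1
            while q >= 0 and gene_buf[q] > v:
                gene_buf[q + 1] = gene_buf[q]
                q -= 1
            gene_buf[q + 1] = v
        for w in range(W):
            mask[w] = np.uint64(0)
        sb = start_bits[j]
        ptr = 0
        for c in range(nc):
            g0 = chrom_first_gene[c]
            g1 = chrom_first_gene[c + 1]
            state = np.int64((sb >> np.uint64(c)) & one)
            cur = g0
            while ptr < k and gene_buf[ptr] < g1:
                nxt = gene_buf[ptr]
                ptr += 1
                if state == 1:
                    _fill_range(mask, gene_first_site[cur], gene_first_site[nxt])
                cur = nxt
                state ^= 1
            if state == 1:
                _fill_range(mask, gene_first_site[cur], gene_first_site[g1])
        p = parent_idx[j]
        r0 = 2 * p
        r1 = r0 + 1
        for w in range(W):
            m = mask[w]
            out[j, w] = (geno[r0, w] & ~m) | (geno[r1, w] & m)


@nb.njit(cache=True)
def count_alleles(geno, n_sites, db_table):
    """Allele count (number of carrying haplotypes) per site."""
    counts = np.zeros(n_sites, dtype=np.int64)
    R, W = geno.shape
    deb = _DEBRUIJN
    s58 = np.uint64(58)
    for r in range(R):
        for w in range(W):
            word = geno[r, w]
            base = w << 6
            while word != np.uint64(0):
                b = word & (~word + np.uint64(1))
                counts[base + db_table[(b * deb) >> s58]] += 1
                word ^= b
    return counts


@nb.njit(cache=True)
def repack(geno, old2new, n_words_new, db_table):
    """Remap site columns (``old2new[i] < 0`` drops site i)."""
    R, W = geno.shape
    out = np.zeros((R, n_words_new), dtype=np.uint64)
    one = np.uint64(1)
    deb = _DEBRUIJN
    s58 = np.uint64(58)
    for r in range(R):
        for w in range(W):
            word = geno[r, w]
            base = w << 6
            while word != np.uint64(0):
                b = word & (~word + np.uint64(1))
                j = old2new[base + db_table[(b * deb) >> s58]]
                if j >= 0:
                    out[r, j >> 6] |= one << np.uint64(j & 63)
                word ^= b
    return out


@nb.njit(cache=True)
def pair_log_fitness(geno, which, log_hom, log_het, db_table, out):
    """Multiplicative fitness over segregating sites for individuals listed
    in ``which`` (rows 2i, 2i+1 of ``geno``); ``out[i]`` gets the product of
    (1+s) over homozygous and (1+h*s) over heterozygous sites (exp of summed
    logs; a homozygous lethal yields exactly 0)."""
    W = geno.shape[1]
    deb = _DEBRUIJN
    s58 = np.uint64(58)
    for t in range(which.shape[0]):
        i = which[t]
        r0 = 2 * i
        r1 = r0 + 1
        acc = 0.0
        for w in range(W):
            a = geno[r0, w]
            b = geno[r1, w]
            hom = a & b
            het = a ^ b
            base = w << 6
            while hom != np.uint64(0):
                bit = hom & (~hom + np.uint64(1))
                acc += log_hom[base + db_table[(bit * deb) >> s58]]
                hom ^= bit
            while het != np.uint64(0):
                bit = het & (~het + np.uint64(1))
                acc += log_het[base + db_table[(bit * deb) >> s58]]
                het ^= bit
        out[i] = np.exp(acc)


@nb.njit(cache=True)
def row_site_indices(row, db_table, out):
    """Indices of set bits in one haplotype row; returns the count."""
    W = row.shape[0]
    deb = _DEBRUIJN
    s58 = np.uint64(58)
    k = 0
    for w in range(W):
        word = row[w]
        base = w << 6
        while word != np.uint64(0):
            b = word & (~word + np.uint64(1))
            out[k] = base + db_table[(b * deb) >> s58]
            k += 1
            word ^= b
    return k


def set_bits(geno: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> None:
    """Set geno[rows[k], cols[k]] bits (vectorized helper, not a kernel)."""
    if len(rows) == 0:
        return
    words = cols >> 6
    masks = np.uint64(1) << np.uint64(cols & 63)
    np.bitwise_or.at(geno, (rows, words), masks)


DB_TABLE = _DB_TABLE
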