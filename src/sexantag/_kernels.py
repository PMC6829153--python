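"""Numba inner loops for the genome-scale simulator.

The production path stores haplotypes sparsely (CSR rows of carried locus
ids, ordered by genomic position); ``transmit_sparse`` and
``log_fitness_sparse`` merge a parent's two sorted rows in position order.
``transmit`` and ``log_fitness`` are the dense reference kernels, retained
as independent implementations for cross-checking.
"""

from __future__ import annotations

import numba as nb


@nb.njit(cache=True)
def transmit(hap, pos, parent_row0, start_hap, bp_flat, bp_off, out):
    """Form gametes by copying alternating parental segments.

    For gamete ``g``, walk the loci in position order starting on haplotype
    ``start_hap[g]`` of the parent whose first haplotype row is
    ``parent_row0[g]``, toggling haplotypes at each crossover breakpoint in
    ``bp_flat[bp_off[g]:bp_off[g+1]]`` (sorted within each gamete).
    """
    n_gam = parent_row0.shape[0]
    n_loci = pos.shape[0]
    for g in range(n_gam):
        r0 = parent_row0[g]
        cur = start_hap[g]
        k = bp_off[g]
        k_end = bp_off[g + 1]
        for j in range(n_loci):
            while k < k_end and bp_flat[k] <= pos[j]:
                cur ^= 1
                k += 1
            out[g, j] = hap[r0 + cur, j]


@nb.njit(cache=True)
def transmit_sparse(
    indices,
    indptr,
    pos,
    parent_row0,
    start_hap,
    bp_flat,
    bp_off,
    out_indices,
    out_ptr_upper,
    out_counts,
):
    """Sparse gamete formation: merge the parent's two haplotype rows.

    Haplotype rows are sorted lists of carried locus ids (ids ordered by
    genomic position).  For each gamete the merged stream of the parent's
    carried loci is walked in position order while advancing that gamete's
    crossover breakpoints; a locus is transmitted when the currently active
    haplotype carries it.  Gamete ``g`` writes its carried ids at
    ``out_indices[out_ptr_upper[g]:...]`` and its count to ``out_counts[g]``.
    """
    n_gam = parent_row0.shape[0]
    for g in range(n_gam):
        ra = parent_row0[g]
        ia, ea = indptr[ra], indptr[ra + 1]
        ib, eb = indptr[ra + 1], indptr[ra + 2]
        k, k_end = bp_off[g], bp_off[g + 1]
        cur = start_hap[g]
        w = out_ptr_upper[g]
        n_out = 0
        while ia < ea or ib < eb:
            if ia < ea and (ib >= eb or indices[ia] <= indices[ib]):
                col = indices[ia]
                in_a = True
                in_b = ib < eb and indices[ib] == col
            else:
                col = indices[ib]
                in_a = False
                in_b = True
            while k < k_end and bp_flat[k] <= pos[col]:
                cur ^= 1
                k += 1
            if (cur == 0 and in_a) or (cur == 1 and in_b):
                out_indices[w + n_out] = col
                n_out += 1
            if in_a:
                ia += 1
            if in_b:
                ib += 1
        out_counts[g] = n_out


@nb.njit(cache=True)
def compact_rows(buf, ptr_upper, counts, out, out_ptr):
    """Copy per-gamete entries from the padded buffer into CSR storage.

    Gamete ``g``'s entries live at ``buf[ptr_upper[g]:ptr_upper[g]+counts[g]]``
    and are copied to ``out[out_ptr[g]:out_ptr[g]+counts[g]]``.
    """
    for g in range(counts.shape[0]):
        src = ptr_upper[g]
        dst = out_ptr[g]
        for j in range(counts[g]):
            out[dst + j] = buf[src + j]


@nb.njit(cache=True)
def log_fitness_sparse(
    indices, indptr, row0, n_ind, sex, lhet_f, lhom_f, lhet_m, lhom_m, out
):
    """Own-sex log multiplicative fitness from sparse haplotype rows.

    Loci present in both of an individual's rows are homozygous, loci in
    exactly one are heterozygous.
    """
    for i in range(n_ind):
        ra = row0 + 2 * i
        ia, ea = indptr[ra], indptr[ra + 1]
        ib, eb = indptr[ra + 1], indptr[ra + 2]
        acc = 0.0
        female = sex[i] == 0
        while ia < ea or ib < eb:
            if ia < ea and (ib >= eb or indices[ia] < indices[ib]):
                col = indices[ia]
                acc += lhet_f[col] if female else lhet_m[col]
                ia += 1
            elif ib < eb and (ia >= ea or indices[ib] < indices[ia]):
                col = indices[ib]
                acc += lhet_f[col] if female else lhet_m[col]
                ib += 1
            else:
                col = indices[ia]
                acc += lhom_f[col] if female else lhom_m[col]
                ia += 1
                ib += 1
        out[i] = acc


@nb.njit(cache=True)
def log_fitness(hap, row0, n_ind, sex, lhet_f, lhom_f, lhet_m, lhom_m, out):
    """Per-individual log multiplicative fitness in its own sex.

    Individual ``i`` occupies haplotype rows ``row0 + 2i`` and
    ``row0 + 2i + 1``; ``lhet``/``lhom`` are per-locus ``log(1 + h*s)`` and
    ``log(1 + s)`` for the relevant sex.
    """
    n_loci = lhet_f.shape[0]
    for i in range(n_ind):
        ra = row0 + 2 * i
        rb = ra + 1
        acc = 0.0
        if sex[i] == 0:
            for j in range(n_loci):
                g = hap[ra, j] + hap[rb, j]
                if g == 1:
                    acc += lhet_f[j]
                elif g == 2:
                    acc += lhom_f[j]
        else:
            for j in range(n_loci):
                g = hap[ra, j] + hap[rb, j]
                if g == 1:
                    acc += lhet_m[j]
                elif g == 2:
                    acc += lhom_m[j]
        out[i] = acc
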