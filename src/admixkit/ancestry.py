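"""Global ancestry from local-ancestry tracts, and local dosage lookup.

Global proportions are obtained by summing the genetic length (cM) of
tracts per ancestry over both haplotypes, after dropping every tract whose
posterior probability falls below a threshold (default 0.9), then
renormalizing so the retained proportions sum to 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (AdmixkitError, FormatError, GlobalAncestry,
                        LocalAncestrySet)


def _tract_cm_lengths(la: LocalAncestrySet) -> np.ndarray:
    """Genetic length (cM) of each tract row, by interpolation on the map."""
    out = np.empty(len(la.tracts))
    for chrom in la.tracts["chrom"].unique():
        mk = la.gmap.markers_on(chrom)
        sel = (la.tracts["chrom"] == chrom).to_numpy()
        s = la.tracts.loc[sel, "spos"].to_numpy(float)
        e = la.tracts.loc[sel, "epos"].to_numpy(float)
        if len(mk) >= 2:
            xp = la.gmap.pos[mk].astype(float)
            fp = la.gmap.cm[mk]
            out[sel] = np.interp(e, xp, fp) - np.interp(s, xp, fp)
        else:  # no usable map on this chromosome: constant 1 cM/Mb fallback
            out[sel] = (e - s) / 1e6
    return out


def compute_global_ancestry(la: LocalAncestrySet,
                            min_posterior: float = 0.9) -> GlobalAncestry:
    """Per-individual ancestry proportions from posterior-filtered tracts.

    Tracts with posterior < ``min_posterior`` are excluded whole; an
    individual with no retained length gets an NA row. ``min_posterior``
    may be 0 (no filter) up to 1.
    """
    if not 0 <= min_posterior <= 1:
        raise AdmixkitError("min_posterior must be in [0, 1]")
    t = la.tracts
    lengths = _tract_cm_lengths(la)
    keep = t["posterior"].to_numpy(float) >= min_posterior
    tally = (pd.DataFrame({"individual": t["individual"],
                           "ancestry": t["ancestry"],
                           "cm": np.where(keep, lengths, 0.0)})
             .pivot_table(index="individual", columns="ancestry",
                          values="cm", aggfunc="sum", fill_value=0.0)
             .reindex(columns=list(la.ancestries), fill_value=0.0)
             .reindex(la.individuals))
    total = tally.sum(axis=1)
    props = tally.div(total, axis=0)
    props[total <= 0] = np.nan
    props.columns.name = None
    props.index.name = "individual"
    return GlobalAncestry(props)


def ancestry_codes_at(la: LocalAncestrySet, chrom, positions,
                      min_posterior: float | None = None):
    """Ancestry code index per (individual, haplotype) at given positions.

    Returns ``(individuals, codes)`` with ``codes`` of shape
    ``(n_individuals, 2, n_positions)``; -1 marks positions covered by a
    tract below ``min_posterior``.
    """
    positions = np.asarray(positions, dtype=np.int64)
    inds = la.individuals
    ind_idx = {v: i for i, v in enumerate(inds)}
    anc_idx = {a: i for i, a in enumerate(la.ancestries)}
    if str(chrom) not in la.chrom_spans:
        raise FormatError(f"no tracts on chromosome {chrom}")
    lo, hi = la.chrom_spans[str(chrom)]
    if positions.min() < lo or positions.max() > hi:
        raise FormatError(
            f"position outside tract coverage [{lo}, {hi}] on "
            f"chromosome {chrom}")
    codes = np.full((len(inds), 2, len(positions)), -1, dtype=np.int8)
    sub = la.tracts[la.tracts["chrom"] == str(chrom)]
    for (ind, hap), g in sub.groupby(["individual", "haplotype"],
                                     sort=False):
        s = g["spos"].to_numpy(np.int64)
        ti = np.searchsorted(s, positions, side="right") - 1
        vals = np.array([anc_idx[a] for a in g["ancestry"]],
                        dtype=np.int8)[ti]
        if min_posterior is not None:
            post = g["posterior"].to_numpy(float)
            vals = np.where(post[ti] < min_posterior, -1, vals)
        codes[ind_idx[ind], int(hap)] = vals
    return inds, codes


def local_dosage_at(la: LocalAncestrySet, ancestry: str, chrom, positions,
                    min_posterior: float | None = None):
    """Count of haplotypes (0-2) carrying ``ancestry`` at each position.

    Positions under a tract excluded by ``min_posterior`` yield NaN for
    that haplotype's contribution.
    Returns ``(individuals, array (n_individuals, n_positions))``.
    """
    if ancestry not in la.ancestries:
        raise AdmixkitError(f"unknown ancestry {ancestry!r}")
    a = la.ancestries.index(ancestry)
    inds, codes = ancestry_codes_at(la, chrom, positions, min_posterior)
    hap = np.where(codes == -1, np.nan, (codes == a).astype(float))
    return inds, hap.sum(axis=1)
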