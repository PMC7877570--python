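"""Core data model shared by every pipeline stage.

Conventions: genomic coordinates are 1-based, closed intervals
``[start_bp, stop_bp]``; ancestry dosage at a locus is the number of
haplotypes (0-2) assigned a given ancestry; global ancestry proportions
sum to 1 per individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Default four-way ancestry coding: Polynesian, European, East Asian, African.
DEFAULT_ANCESTRIES = ("PNS", "EUR", "EAS", "AFR")


class AdmixkitError(Exception):
    """Base class for all package errors."""


class FormatError(AdmixkitError):
    """Malformed input file or violated structural invariant."""


class ModelError(AdmixkitError):
    """Statistical model cannot be fit as requested."""


@dataclass(frozen=True)
class GenomicMap:
    """Marker grid: physical (bp) and genetic (cM) positions per chromosome.

    Parameters
    ----------
    chrom : array of str
        Chromosome label per marker.
    pos : array of int
        1-based physical positions, strictly increasing within chromosome.
    cm : array of float
        Genetic positions in centimorgans, non-decreasing within chromosome.
    """

    chrom: np.ndarray
    pos: np.ndarray
    cm: np.ndarray

    def __post_init__(self):
        chrom = np.asarray(self.chrom, dtype=object)
        pos = np.asarray(self.pos, dtype=np.int64)
        cm = np.asarray(self.cm, dtype=float)
        if not (len(chrom) == len(pos) == len(cm)):
            raise FormatError("chrom/pos/cm must have equal length")
        for c in pd.unique(chrom):
            m = chrom == c
            if np.any(np.diff(pos[m]) <= 0):
                raise FormatError(
                    f"positions not strictly increasing on chromosome {c}")
            if np.any(np.diff(cm[m]) < 0):
                raise FormatError(
                    f"genetic positions decreasing on chromosome {c}")
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "pos", pos)
        object.__setattr__(self, "cm", cm)

    @classmethod
    def constant_rate(cls, chrom_lengths: dict[str, int], n_markers: int,
                      rate_cm_per_mb: float = 1.0) -> "GenomicMap":
        """Evenly spaced markers under a constant recombination rate.

        ``n_markers`` is the total marker count, split across chromosomes
        proportionally to physical length. The default 1 cM/Mb mirrors the
        robustness of local-ancestry inference to a flat map.
        """
        total = sum(chrom_lengths.values())
        chroms, poss, cms = [], [], []
        for c, L in chrom_lengths.items():
            k = max(2, round(n_markers * L / total))
            p = np.unique(np.linspace(1, L, k).astype(np.int64))
            chroms.append(np.full(len(p), c, dtype=object))
            poss.append(p)
            cms.append(p / 1e6 * rate_cm_per_mb)
        return cls(np.concatenate(chroms), np.concatenate(poss),
                   np.concatenate(cms))

    @property
    def chromosomes(self) -> list[str]:
        return list(pd.unique(self.chrom))

    @property
    def n_markers(self) -> int:
        return len(self.pos)

    def markers_on(self, chrom: str) -> np.ndarray:
        """Indices of markers on one chromosome, in map order."""
        return np.nonzero(self.chrom == chrom)[0]

    def total_morgans(self) -> float:
        """Genetic length summed over chromosomes, in Morgans."""
        tot = 0.0
        for c in self.chromosomes:
            cm = self.cm[self.chrom == c]
            tot += (cm[-1] - cm[0]) / 100.0
        return tot


TRACT_COLUMNS = ["individual", "haplotype", "chrom", "spos", "epos",
                 "ancestry", "posterior"]


@dataclass
class LocalAncestrySet:
    """Per-haplotype ancestry tracts along the genome.

    ``tracts`` holds one row per tract: individual id, haplotype (0 or 1),
    chromosome, start/stop bp (1-based closed), ancestry code, and the
    tract's posterior probability. Tracts of one haplotype must tile each
    chromosome without gap or overlap.
    """

    tracts: pd.DataFrame
    gmap: GenomicMap
    ancestries: tuple[str, ...] = DEFAULT_ANCESTRIES

    def __post_init__(self):
        missing = [c for c in TRACT_COLUMNS if c not in self.tracts.columns]
        if missing:
            raise FormatError(f"tract table missing columns: {missing}")
        bad = set(self.tracts["ancestry"]) - set(self.ancestries)
        if bad:
            raise FormatError(f"unknown ancestry code(s): {sorted(bad)}")
        post = self.tracts["posterior"].to_numpy(float)
        if np.any((post < 0) | (post > 1)):
            raise FormatError("tract posterior outside [0, 1]")
        self.tracts = self.tracts[TRACT_COLUMNS].sort_values(
            ["individual", "haplotype", "chrom", "spos"], kind="mergesort"
        ).reset_index(drop=True)
        self._validate_tiling()

    def _validate_tiling(self):
        spans: dict[str, tuple[int, int]] = {}
        for (ind, hap, chrom), g in self.tracts.groupby(
                ["individual", "haplotype", "chrom"], sort=False):
            s = g["spos"].to_numpy(np.int64)
            e = g["epos"].to_numpy(np.int64)
            if np.any(e < s):
                raise FormatError(
                    f"tract with stop < start: {ind} hap {hap} chr {chrom}")
            gaps = s[1:] - e[:-1]
            if np.any(gaps != 1):
                i = int(np.nonzero(gaps != 1)[0][0])
                kind = "overlap" if gaps[i] < 1 else "gap"
                raise FormatError(
                    f"{kind} between tracts on {ind} haplotype {hap} "
                    f"chromosome {chrom}: [{s[i]},{e[i]}] then "
                    f"[{s[i + 1]},{e[i + 1]}]")
            span = (int(s[0]), int(e[-1]))
            if spans.setdefault(chrom, span) != span:
                raise FormatError(
                    f"haplotypes disagree on the extent of chromosome "
                    f"{chrom}: {spans[chrom]} vs {span}")
        self.chrom_spans = spans

    @property
    def individuals(self) -> list:
        return list(pd.unique(self.tracts["individual"]))

    def _hap_ancestry_at_markers(self, min_posterior: float | None = None):
        """Ancestry code index per (individual, haplotype, marker).

        Returns an int array of shape (n_individuals, 2, n_markers) with -1
        where the covering tract's posterior falls below ``min_posterior``.
        """
        inds = self.individuals
        ind_idx = {v: i for i, v in enumerate(inds)}
        anc_idx = {a: i for i, a in enumerate(self.ancestries)}
        out = np.full((len(inds), 2, self.gmap.n_markers), -1, dtype=np.int8)
        for (ind, hap, chrom), g in self.tracts.groupby(
                ["individual", "haplotype", "chrom"], sort=False):
            mk = self.gmap.markers_on(chrom)
            if len(mk) == 0:
                continue
            mpos = self.gmap.pos[mk]
            s = g["spos"].to_numpy(np.int64)
            lo, hi = self.chrom_spans[chrom]
            if mpos[0] < lo or mpos[-1] > hi:
                raise FormatError(
                    f"marker outside tract coverage on chromosome {chrom}")
            ti = np.searchsorted(s, mpos, side="right") - 1
            codes = np.array([anc_idx[a] for a in g["ancestry"]], dtype=np.int8)
            vals = codes[ti]
            if min_posterior is not None:
                post = g["posterior"].to_numpy(float)
                vals = np.where(post[ti] < min_posterior, -1, vals)
            out[ind_idx[ind], int(hap), mk] = vals
        return inds, out

    def dosage(self, ancestry: str, min_posterior: float | None = None):
        """Ancestry dosage (0-2) per individual per marker.

        Markers covered by a tract with posterior below ``min_posterior``
        on either haplotype contribute NaN for that haplotype.
        Returns ``(individuals, array (n_individuals, n_markers))``.
        """
        if ancestry not in self.ancestries:
            raise FormatError(f"unknown ancestry {ancestry!r}")
        a = self.ancestries.index(ancestry)
        inds, codes = self._hap_ancestry_at_markers(min_posterior)
        hap = np.where(codes == -1, np.nan, (codes == a).astype(float))
        return inds, hap.sum(axis=1)


@dataclass
class GlobalAncestry:
    """Per-individual global ancestry proportions (rows sum to 1 or are NA)."""

    proportions: pd.DataFrame  # index: individual, columns: ancestry codes

    def __post_init__(self):
        q = self.proportions.to_numpy(float)
        finite = ~np.isnan(q).any(axis=1)
        if np.any((q[finite] < -1e-12) | (q[finite] > 1 + 1e-12)):
            raise FormatError("ancestry proportion outside [0, 1]")
        if np.any(np.abs(q[finite].sum(axis=1) - 1.0) > 1e-9):
            raise FormatError("ancestry proportions do not sum to 1")

    @property
    def ancestries(self) -> list[str]:
        return list(self.proportions.columns)


@dataclass
class DosageMatrix:
    """Imputed allele dosages: samples x variants, values in [0, 2].

    ``variants`` has one row per variant: chrom, pos, ref, alt (the derived
    allele), info (imputation quality in [0, 1]); optionally an ``id``.
    """

    variants: pd.DataFrame
    samples: list
    dosages: np.ndarray  # shape (n_samples, n_variants)

    def __post_init__(self):
        need = {"chrom", "pos", "ref", "alt", "info"}
        missing = need - set(self.variants.columns)
        if missing:
            raise FormatError(f"variant table missing columns: {missing}")
        d = np.asarray(self.dosages, dtype=float)
        if d.shape != (len(self.samples), len(self.variants)):
            raise FormatError("dosage array shape mismatch")
        ok = np.isnan(d) | ((d >= 0) & (d <= 2))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            v = self.variants.iloc[j]
            raise FormatError(
                f"dosage {d[i, j]} outside [0,2] at {v['chrom']}:{v['pos']} "
                f"sample {self.samples[i]}")
        for c in pd.unique(self.variants["chrom"]):
            p = self.variants.loc[self.variants["chrom"] == c, "pos"]
            if np.any(np.diff(p.to_numpy(np.int64)) < 0):
                raise FormatError(f"variants unsorted on chromosome {c}")
        self.dosages = d

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def allele_freq(self) -> np.ndarray:
        """Sample frequency of the alt (derived) allele per variant."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def subset(self, variant_mask) -> "DosageMatrix":
        mask = np.asarray(variant_mask)
        return DosageMatrix(self.variants.loc[mask].reset_index(drop=True),
                            list(self.samples), self.dosages[:, mask])


QUANTITATIVE = "quantitative"
BINARY = "binary"


@dataclass
class CohortTable:
    """Phenotypes plus covariates, one row per individual.

    ``trait_types`` maps trait column name to "quantitative" or "binary".
    Binary traits are coded 0/1; education is ordinal 1-4; nSES is a
    quintile 1-5; census_tract is a cluster label.
    """

    data: pd.DataFrame  # index: individual id
    trait_types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for t, kind in self.trait_types.items():
            if t not in self.data.columns:
                raise FormatError(f"trait {t!r} not in cohort table")
            if kind not in (QUANTITATIVE, BINARY):
                raise FormatError(f"unknown trait type {kind!r}")
            if kind == BINARY:
                v = self.data[t].dropna().unique()
                if not set(v) <= {0, 1}:
                    raise FormatError(f"binary trait {t!r} not coded 0/1")
        if "education" in self.data.columns:
            v = self.data["education"].dropna().unique()
            if not set(v) <= {1, 2, 3, 4}:
                raise FormatError("education levels must be in 1..4")
        if "nses" in self.data.columns:
            v = self.data["nses"].dropna().unique()
            if not set(v) <= {1, 2, 3, 4, 5}:
                raise FormatError("nSES must be a quintile in 1..5")

    @property
    def individuals(self) -> list:
        return list(self.data.index)


@dataclass
class ScanResult:
    """Per-locus (or per-variant) association results.

    ``table`` columns: chrom, pos, beta, se, p, n (+ optional id / reason).
    beta/se/p are jointly NA for loci where the model could not be fit.
    """

    table: pd.DataFrame
    model: str = ""
    covariates: tuple[str, ...] = ()
    conditioning: tuple[str, ...] = ()

    def __post_init__(self):
        need = {"chrom", "pos", "beta", "se", "p"}
        missing = need - set(self.table.columns)
        if missing:
            raise FormatError(f"scan table missing columns: {missing}")
        t = self.table
        fin = t["beta"].notna()
        if not (t.loc[fin, "se"].gt(0).all()
                and t.loc[fin, "p"].between(0, 1, inclusive="right").all()):
            raise FormatError("finite rows need se > 0 and p in (0, 1]")
        if not (t.loc[~fin, "se"].isna().all()
                and t.loc[~fin, "p"].isna().all()):
            raise FormatError("beta/se/p must be NA jointly")

    def min_p(self) -> float:
        p = self.table["p"].to_numpy(float)
        return np.nan if np.isnan(p).all() else float(np.nanmin(p))


@dataclass
class RegionSet:
    """Signal and broad intervals derived from a scan.

    One row per region: chrom, start, stop, kind ("signal" | "broad"),
    peak_neglog10p, and region_id linking each signal region to the broad
    region that contains it.
    """

    regions: pd.DataFrame

    def __post_init__(self):
        need = {"chrom", "start", "stop", "kind", "peak_neglog10p",
                "region_id"}
        missing = need - set(self.regions.columns)
        if missing:
            raise FormatError(f"region table missing columns: {missing}")
        r = self.regions
        if (r["start"] > r["stop"]).any():
            raise FormatError("region with start > stop")
        broad = r[r["kind"] == "broad"].set_index("region_id")
        for _, row in r[r["kind"] == "signal"].iterrows():
            b = broad.loc[row["region_id"]]
            if not (b["start"] <= row["start"] and row["stop"] <= b["stop"]):
                raise FormatError("signal region not nested in broad region")

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.regions[self.regions["kind"] == kind].reset_index(
            drop=True)
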