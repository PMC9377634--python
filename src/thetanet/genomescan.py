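"""Sliding-window theta estimation along a chromosome.

Extracts per-site derived-allele counts from a VCF, aggregates them into
window-wise site frequency spectra and applies any set of theta estimators to
each window.  With a recombination map supplied, every window is annotated
with its total scaled recombination rate and a qualitative regime bin, so
window estimates can be summarized separately for cold, intermediate and hot
recombination regions.

Conventions: positions and windows are 0-based half-open; the REF allele is
taken as ancestral unless an ``AA`` INFO tag says otherwise; sites with any
missing genotype are excluded (the SFS needs complete counts) and tallied in
the returned log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .simulate import RecombinationMap

__all__ = [
    "WindowConfig",
    "VariantCounts",
    "read_variants",
    "sliding_window_sfs",
    "scan_estimates",
    "scaled_theta",
    "rho_regime",
]

logger = logging.getLogger(__name__)

#: Regime bins for windowed scaled recombination rates: low (0, 1],
#: medium (30, 40], high (150, inf); anything else is "other".
RHO_REGIMES = {"low": (0.0, 1.0), "medium": (30.0, 40.0),
               "high": (150.0, np.inf)}


def scaled_theta(mu: float, n_e: float, length: float) -> float:
    """Population-scaled mutation rate ``4 N_e mu L`` of a window.

    ``mu`` is the per-base-pair per-generation mutation rate, ``n_e`` the
    effective population size and ``length`` the window size in bp.  E.g. a
    70 kb window at ``mu = 1.29e-8`` and ``N_e = 1e4`` carries
    ``theta = 36.12``.
    """
    if mu < 0 or n_e <= 0 or length <= 0:
        raise ValueError("need mu >= 0, n_e > 0, length > 0")
    return 4.0 * n_e * mu * length


def rho_regime(rho: float) -> str:
    """Bin a window's scaled recombination rate into low/medium/high/other."""
    for name, (lo, hi) in RHO_REGIMES.items():
        if lo < rho <= hi:
            return name
    return "other"


@dataclass(frozen=True)
class WindowConfig:
    """Window geometry: ``step == window_size`` gives disjoint windows."""

    window_size: int = 70_000
    step: int | None = None
    n: int | None = None  # haploid sample size; inferred from data if None

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        step = self.step if self.step is not None else self.window_size
        if step <= 0 or step > self.window_size:
            raise ValueError("need 0 < step <= window_size")
        object.__setattr__(self, "step", step)


@dataclass
class VariantCounts:
    """Per-site derived-allele counts (0-based positions, sorted)."""

    positions: np.ndarray
    counts: np.ndarray
    n: int
    skipped: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.positions) != len(self.counts):
            raise ValueError("positions and counts must align")
        if np.any(np.diff(self.positions) < 0):
            raise ValueError("positions must be sorted")
        if len(self.counts) and not (
            np.all(self.counts >= 1) and np.all(self.counts <= self.n - 1)
        ):
            raise ValueError("derived counts must lie in 1..n-1")

    def genome_sfs(self) -> np.ndarray:
        """Whole-chromosome SFS ``S_1..S_{n-1}``."""
        return np.bincount(self.counts, minlength=self.n)[1:self.n]


def read_variants(vcf_path, ancestral_tag: str = "AA") -> VariantCounts:
    """Read biallelic SNVs from a VCF into derived-allele counts.

    The REF allele is assumed ancestral; when the INFO field named by
    ``ancestral_tag`` is present and equals the ALT allele, the polarity is
    flipped.  Multiallelic records, non-SNVs and sites with missing genotypes
    are skipped and counted in ``skipped``.
    """
    from cyvcf2 import VCF

    skipped = {"multiallelic": 0, "non_snv": 0, "missing_genotype": 0}
    positions, counts = [], []
    n_alleles = None
    for variant in VCF(str(vcf_path)):
        if len(variant.ALT) != 1:
            skipped["multiallelic"] += 1
            continue
        if len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            skipped["non_snv"] += 1
            continue
        gts = np.asarray(variant.genotypes, dtype=np.int64)[:, :-1]  # drop phase
        alleles = gts[gts > -2].ravel() if gts.ndim else gts  # haploid pads with -2
        site_n = alleles.size
        if n_alleles is None:
            n_alleles = site_n
        elif site_n != n_alleles:
            raise ValueError(
                f"inconsistent ploidy/sample count at {variant.POS}: "
                f"{site_n} vs {n_alleles} alleles"
            )
        if np.any(alleles < 0):
            skipped["missing_genotype"] += 1
            continue
        derived = int(np.sum(alleles == 1))
        aa = variant.INFO.get(ancestral_tag)
        if aa is not None and str(aa).upper() == variant.ALT[0].upper():
            derived = n_alleles - derived
        if 1 <= derived <= n_alleles - 1:
            positions.append(variant.start)  # 0-based
            counts.append(derived)
    if n_alleles is None:
        n_alleles = 2  # empty VCF: no sites, sample size unknown
    if any(skipped.values()):
        logger.info("read_variants skipped sites: %s", skipped)
    order = np.argsort(np.asarray(positions, dtype=np.int64), kind="stable")
    return VariantCounts(
        np.asarray(positions, dtype=np.int64)[order],
        np.asarray(counts, dtype=np.int64)[order],
        n_alleles,
        skipped,
    )


def sliding_window_sfs(
    variants: VariantCounts,
    config: WindowConfig,
    chrom_length: int | None = None,
) -> pd.DataFrame:
    """Window-wise SFS along the chromosome.

    Windows ``[k*step, k*step + window_size)`` are anchored at position 0 and
    advance by ``step``; the final window may extend past the last variant
    (or past ``chrom_length``) and is flagged ``partial``.  Returns a frame
    with ``start``, ``end``, ``partial`` and one ``S_i`` column per frequency
    class; empty windows hold all-zero spectra.
    """
    n = config.n or variants.n
    size, step = config.window_size, config.step
    end_coord = chrom_length
    if end_coord is None:
        end_coord = int(variants.positions[-1]) + 1 if len(variants.positions) else size
    n_windows = max(1, -(-max(end_coord - size, 0) // step) + 1)
    rows = []
    for w in range(n_windows):
        start = w * step
        stop = start + size
        lo, hi = np.searchsorted(variants.positions, [start, stop])
        sfs = np.bincount(variants.counts[lo:hi], minlength=n)[1:n]
        rows.append((start, stop, stop > end_coord, *sfs))
    cols = ["start", "end", "partial"] + [f"S_{i}" for i in range(1, n)]
    return pd.DataFrame(rows, columns=cols)


def scan_estimates(
    windows: pd.DataFrame,
    estimators: Sequence[Callable[[np.ndarray], np.ndarray]],
    rec_map: RecombinationMap | None = None,
) -> pd.DataFrame:
    """Apply theta estimators window by window.

    Adds one column per estimator (named by its ``name`` attribute), the
    segregating-site count, and — when a recombination map is given — the
    window's total scaled rho and its regime bin (low/medium/high per the
    window-rho thresholds in :data:`RHO_REGIMES`).
    """
    s_cols = [c for c in windows.columns if c.startswith("S_")]
    sfs = windows[s_cols].to_numpy()
    out = windows[["start", "end", "partial"]].copy()
    out["segregating_sites"] = sfs.sum(axis=1)
    for est in estimators:
        values = np.asarray(est(sfs), dtype=float)
        out[getattr(est, "name", "estimator")] = values
    if rec_map is not None:
        rhos = np.array(
            [rec_map.window_rho(s, e) for s, e in zip(out["start"], out["end"])]
        )
        out["rho"] = rhos
        out["regime"] = [rho_regime(r) for r in rhos]
    return out
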