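"""Site frequency spectrum containers and TSV serialization.

The unfolded site frequency spectrum (SFS) of a sample of ``n`` haploid
sequences is the vector ``S = (S_1, ..., S_{n-1})`` where ``S_i`` counts the
segregating sites at which exactly ``i`` sequences carry the derived allele.
The ancestral state is assumed known (infinitely-many-sites model), so the
spectrum is not folded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SiteFrequencySpectrum", "SFSDataset"]


@dataclass(frozen=True)
class SiteFrequencySpectrum:
    """An unfolded SFS for a sample of ``n`` haploid sequences.

    Parameters
    ----------
    counts
        Integer vector of length ``n - 1``; ``counts[i - 1]`` is the number of
        segregating sites with derived-allele count ``i``.
    n
        Haploid sample size, at least 2.
    """

    counts: np.ndarray
    n: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if self.n < 2:
            raise ValueError(f"sample size must be >= 2, got n={self.n}")
        if counts.ndim != 1 or counts.shape[0] != self.n - 1:
            raise ValueError(
                f"SFS for n={self.n} must have length {self.n - 1}, "
                f"got shape {counts.shape}"
            )
        if np.any(counts < 0):
            raise ValueError("SFS counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def segregating_sites(self) -> int:
        """Total number of segregating sites ``M = sum_i S_i``."""
        return int(self.counts.sum())

    def __len__(self) -> int:
        return self.counts.shape[0]


@dataclass
class SFSDataset:
    """A matrix of SFS replicates with per-row true parameters.

    Rows of ``sfs`` are independent replicates; ``theta`` and ``rho`` hold the
    scaled mutation and recombination rates each row was generated under.
    ``rho`` may contain ``inf`` for the unlinked-loci (free recombination)
    limit.
    """

    sfs: np.ndarray
    theta: np.ndarray
    rho: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sfs = np.atleast_2d(np.asarray(self.sfs))
        self.theta = np.broadcast_to(
            np.asarray(self.theta, dtype=float), (self.sfs.shape[0],)
        ).copy()
        if self.rho is None:
            self.rho = np.zeros(self.sfs.shape[0])
        self.rho = np.broadcast_to(
            np.asarray(self.rho, dtype=float), (self.sfs.shape[0],)
        ).copy()
        if np.any(self.theta < 0):
            raise ValueError("theta labels must be non-negative")

    @property
    def n(self) -> int:
        """Haploid sample size implied by the number of SFS columns."""
        return self.sfs.shape[1] + 1

    def __len__(self) -> int:
        return self.sfs.shape[0]

    def row(self, i: int) -> SiteFrequencySpectrum:
        return SiteFrequencySpectrum(self.sfs[i], self.n)

    def subset(self, mask: np.ndarray) -> "SFSDataset":
        return SFSDataset(self.sfs[mask], self.theta[mask], self.rho[mask])

    @staticmethod
    def concat(datasets: list["SFSDataset"]) -> "SFSDataset":
        if not datasets:
            raise ValueError("need at least one dataset to concatenate")
        return SFSDataset(
            np.vstack([d.sfs for d in datasets]),
            np.concatenate([d.theta for d in datasets]),
            np.concatenate([d.rho for d in datasets]),
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {f"S_{i}": self.sfs[:, i - 1] for i in range(1, self.n)}
        cols["theta"] = self.theta
        cols["rho"] = self.rho
        return pd.DataFrame(cols)

    def to_tsv(self, path) -> None:
        """Write as TSV with header columns ``S_1..S_{n-1}, theta, rho``."""
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SFSDataset":
        df = pd.read_csv(path, sep="\t")
        s_cols = [c for c in df.columns if c.startswith("S_")]
        s_cols.sort(key=lambda c: int(c.split("_")[1]))
        theta = df["theta"].to_numpy() if "theta" in df else np.zeros(len(df))
        rho = df["rho"].to_numpy() if "rho" in df else np.zeros(len(df))
        return cls(df[s_cols].to_numpy(), theta, rho)
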