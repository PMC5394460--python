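"""PCA preparation (singleton removal, windowed LD pruning) and PCA proper.

The pruning scheme follows the common variant-tool convention: windows of a
fixed number of SNPs advanced by a fixed step; within each window, for every
ordered pair of still-retained loci whose dosage correlation exceeds the r^2
ceiling, the later locus is dropped and stays dropped.

PCA uses Patterson scaling: each locus is centred by its mean dosage and
divided by sqrt(p(1-p)) with p = mean/2, the binomial standard deviation of a
single allele draw.  Eigenvalues are those of the locus-averaged sample
covariance (the genetic relationship matrix X X^T / m).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["GenotypeMatrix", "remove_singletons", "ld_prune", "pca", "PcaResult"]


@dataclass
class GenotypeMatrix:
    """Samples x loci dosage matrix with locus metadata.

    ``dosages`` holds alt-allele counts in {0,1,2} (no missing values —
    matrices enter PCA downstream of the missingless filter); ``loci`` has
    columns ``chrom`` and ``pos`` and is sorted by (chrom, pos) within arm.
    """

    dosages: np.ndarray
    samples: list[str]
    loci: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.shape != (len(self.samples), len(self.loci)):
            raise ValueError("dosage shape does not match samples x loci")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def take_loci(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosages[:, idx], list(self.samples), self.loci.iloc[idx].reset_index(drop=True)
        )

    def restrict_to_arms(self, arms) -> "GenotypeMatrix":
        mask = self.loci["chrom"].isin(list(arms)).to_numpy()
        return self.take_loci(np.nonzero(mask)[0])


def remove_singletons(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Drop loci with minor-allele count <= 1 (monomorphic loci included)."""
    ac = gm.dosages.sum(axis=0)
    mac = np.minimum(ac, 2 * gm.n_samples - ac)
    return gm.take_loci(np.nonzero(mac > 1)[0])


def ld_prune(
    dosages: np.ndarray, window: int = 500, step: int = 100, r2_max: float = 0.1
) -> np.ndarray:
    """Greedy left-to-right LD pruning; returns retained locus indices.

    For each window [s, s+window) with s advancing by ``step``, ordered pairs
    of still-retained loci with squared Pearson dosage correlation > ``r2_max``
    cause removal of the later locus.  Zero-variance loci cannot be correlated
    with anything and are treated as r^2 = 0 (logged).
    """
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if n < 2:
        raise ValueError("LD pruning requires at least two samples")
    keep = np.ones(m, dtype=bool)
    sd = dosages.std(axis=0)
    zero_var = sd == 0
    if zero_var.any():
        logger.info("ld_prune: %d zero-variance loci treated as uncorrelated", zero_var.sum())
    centred = dosages - dosages.mean(axis=0)
    denom = np.where(zero_var, 1.0, sd * np.sqrt(n))
    z = centred / denom  # unit-norm columns (zero for invariant loci)
    starts = range(0, m, step) if m > 0 else []
    for s in starts:
        idx = np.nonzero(keep[s : s + window])[0] + s
        if len(idx) < 2:
            continue
        r = z[:, idx].T @ z[:, idx]
        r2 = r * r
        live = np.ones(len(idx), dtype=bool)
        for i in range(len(idx)):
            if not live[i] or zero_var[idx[i]]:
                continue
            for j in range(i + 1, len(idx)):
                if live[j] and r2[i, j] > r2_max:
                    live[j] = False
        keep[idx[~live]] = False
        if s + window >= m:
            break
    return np.nonzero(keep)[0]


def ld_prune_matrix(
    gm: GenotypeMatrix, window: int = 500, step: int = 100, r2_max: float = 0.1
) -> GenotypeMatrix:
    """Prune per arm (windows never straddle an arm boundary)."""
    kept: list[np.ndarray] = []
    for arm in gm.loci["chrom"].unique():
        arm_idx = np.nonzero((gm.loci["chrom"] == arm).to_numpy())[0]
        sub = ld_prune(gm.dosages[:, arm_idx], window=window, step=step, r2_max=r2_max)
        kept.append(arm_idx[sub])
    return gm.take_loci(np.concatenate(kept) if kept else np.array([], dtype=int))


@dataclass
class PcaResult:
    coordinates: pd.DataFrame  # samples x PCs
    eigenvalues: np.ndarray
    total_variance: float  # trace of the scaled covariance; equals sum of all eigenvalues


def pca(gm: GenotypeMatrix, k: int = 10, scaling: str = "patterson") -> PcaResult:
    """Principal components of the scaled genotype matrix.

    ``scaling='patterson'`` (default) divides centred dosages by
    sqrt(p(1-p)); ``scaling='center'`` only centres.  Components are ordered
    by decreasing eigenvalue with a deterministic sign convention: the
    largest-magnitude sample coordinate on each axis is positive.
    """
    if gm.n_samples < 2:
        raise ValueError("PCA requires at least two samples")
    if gm.n_loci < 1:
        raise ValueError("PCA requires at least one locus")
    x = np.asarray(gm.dosages, dtype=float)
    mean = x.mean(axis=0)
    x = x - mean
    if scaling == "patterson":
        p = mean / 2.0
        scale = np.sqrt(p * (1.0 - p))
        poly = scale > 0
        x = x[:, poly] / scale[poly]
    elif scaling != "center":
        raise ValueError(f"unknown scaling {scaling!r}")
    m = x.shape[1]
    if m == 0:
        raise ValueError("no polymorphic loci left for PCA")
    grm = (x @ x.T) / m
    eigvals, eigvecs = np.linalg.eigh(grm)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    k = min(k, len(eigvals))
    coords = eigvecs[:, :k] * np.sqrt(np.maximum(eigvals[:k], 0.0))
    for j in range(k):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    frame = pd.DataFrame(
        coords, index=pd.Index(gm.samples, name="sample"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PcaResult(coordinates=frame, eigenvalues=eigvals, total_variance=float(np.trace(grm)))
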