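"""Case-control association Z scores from individual-level dosages.

This is the genotype-based route that summary-statistics imputation is
validated against: given a dosage matrix and a binary phenotype, each
marker gets a signed score-test (Cochran-Armitage trend-type) Z,

    Z = sum_i (y_i - ybar) g_i / sqrt( ybar (1 - ybar) sum_i (g_i - gbar)^2 )

with Z > 0 meaning the counted allele is enriched in cases.  The score
test is covariate-free and asymptotically equivalent to the logistic
Wald Z under the null, which matches the imputation method's own
no-covariate regime.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from .panel import Marker

logger = logging.getLogger(__name__)


class MonomorphicError(ValueError):
    """Dosage or phenotype vector is constant; the trend Z is undefined."""


@dataclass
class GenotypeMatrix:
    """N x M dosage matrix with marker metadata and a 0/1 phenotype."""

    dosages: np.ndarray
    markers: list[Marker]
    y: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.y = np.asarray(self.y)
        n, m = self.dosages.shape
        if m != len(self.markers):
            raise ValueError(f"{len(self.markers)} markers, {m} dosage columns")
        if self.y.shape != (n,):
            raise ValueError(f"phenotype length {self.y.shape} != {n} samples")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("phenotypes must be 0/1")
        if not np.isfinite(self.dosages).all():
            raise ValueError("dosages must be finite")
        if self.y.min() == self.y.max():
            raise ValueError("need at least one case and one control")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_cases(self) -> int:
        return int(self.y.sum())


def trend_test_z(dosages: np.ndarray, y: np.ndarray) -> float:
    """Signed score-test Z for one marker's dosage vector.

    Positive when the counted allele is enriched in cases.  Raises
    :class:`MonomorphicError` on a constant dosage or phenotype vector
    rather than returning a number.
    """
    g = np.asarray(dosages, dtype=float)
    y = np.asarray(y, dtype=float)
    if g.shape != y.shape:
        raise ValueError(f"dosage shape {g.shape} != phenotype shape {y.shape}")
    if g.min() == g.max():
        raise MonomorphicError("monomorphic dosage vector")
    if y.min() == y.max():
        raise MonomorphicError("constant phenotype vector")
    ybar = y.mean()
    num = ((y - ybar) * g).sum()
    den = np.sqrt(ybar * (1.0 - ybar) * ((g - g.mean()) ** 2).sum())
    return float(num / den)


def cohort_scan(
    genos: GenotypeMatrix,
    kinds: set | None = None,
) -> pd.DataFrame:
    """Trend-test every polymorphic marker; return a summary-stats table.

    Vectorised equivalent of calling :func:`trend_test_z` per column.
    Monomorphic markers are skipped with a logged count.  ``kinds``
    optionally restricts output to the given marker kinds (e.g. SNPs
    only, to build the typed input of an imputation run).
    """
    g = genos.dosages
    y = genos.y.astype(float)
    keep = np.array(
        [
            (kinds is None or mk.kind in kinds) and g[:, j].min() != g[:, j].max()
            for j, mk in enumerate(genos.markers)
        ]
    )
    n_mono = sum(
        1
        for j, mk in enumerate(genos.markers)
        if (kinds is None or mk.kind in kinds) and g[:, j].min() == g[:, j].max()
    )
    if n_mono:
        logger.info("cohort scan: skipped %d monomorphic markers", n_mono)

    gk = g[:, keep]
    ybar = y.mean()
    num = (y - ybar) @ gk
    den = np.sqrt(ybar * (1.0 - ybar) * ((gk - gk.mean(axis=0)) ** 2).sum(axis=0))
    z = num / den

    kept = [mk for j, mk in enumerate(genos.markers) if keep[j]]
    return pd.DataFrame(
        {
            "id": [mk.id for mk in kept],
            "pos": [mk.position for mk in kept],
            "a1": [mk.counted_allele for mk in kept],
            "a2": [mk.other_allele for mk in kept],
            "z": z,
        }
    )


def compare_z(
    set_a: pd.DataFrame,
    set_b: pd.DataFrame,
    r2pred_min: float = 0.5,
) -> tuple[float, float, int]:
    """Pearson and Spearman correlation of two Z tables over shared variants.

    Tables are joined on ``id``; a row survives the reliability filter
    when every ``r2pred`` column present (in either table) is
    ``>= r2pred_min``.  Requires at least 3 shared variants.
    """
    a = set_a.set_index("id")
    b = set_b.set_index("id")
    merged = a.join(b, how="inner", lsuffix="_a", rsuffix="_b")
    for col in ("r2pred", "r2pred_a", "r2pred_b"):
        if col in merged.columns:
            merged = merged[merged[col] >= r2pred_min]
    za = merged["z_a"] if "z_a" in merged.columns else merged["z"]
    zb = merged["z_b"] if "z_b" in merged.columns else merged["z"]
    n = len(merged)
    if n < 3:
        raise ValueError(
            f"only {n} shared variants after the r2pred >= {r2pred_min} filter; "
            "need at least 3 to correlate"
        )
    pearson = scipy.stats.pearsonr(za, zb).statistic
    spearman = scipy.stats.spearmanr(za, zb).statistic
    return float(pearson), float(spearman), n


# ---------------------------------------------------------------------------
# File input
# ---------------------------------------------------------------------------

def read_genotype_matrix(
    dosage_path: str | Path,
    phenotype_path: str | Path,
    markers: list[Marker] | None = None,
) -> GenotypeMatrix:
    """Read dosages (markers x samples TSV) and a phenotype file (id, 0/1).

    The dosage table's first column is the marker id and its header row
    names the samples; the phenotype file pairs sample ids with 0/1
    status.  Samples are intersected and ordered as in the dosage file.
    When ``markers`` metadata is not given, minimal metadata is inferred
    from marker ids (HLA_/AA_ naming) as in the haplotype-table reader.
    """
    from .panel import MarkerKind, _infer_kind

    dos = pd.read_csv(dosage_path, sep="\t", index_col=0)
    phen = pd.read_csv(
        phenotype_path, sep="\t", header=None, names=["sample", "y"], dtype={0: str}
    )
    phen = phen.set_index("sample")["y"]
    samples = [s for s in dos.columns if s in phen.index]
    if not samples:
        raise ValueError("no shared sample ids between dosage and phenotype files")
    dos = dos[samples]

    if markers is None:
        markers = []
        for mid in dos.index:
            kind = _infer_kind(str(mid))
            if kind is None:
                kind = MarkerKind.SNP
                counted, other = "A", "G"  # placeholder alleles for bare ids
            else:
                counted, other = "P", "A"
            markers.append(Marker(str(mid), kind, 0, counted, other, 0.5))
    else:
        by_id = {m.id: m for m in markers}
        missing = [mid for mid in dos.index if mid not in by_id]
        if missing:
            raise ValueError(f"markers missing metadata: {missing[:5]}")
        markers = [by_id[mid] for mid in dos.index]

    return GenotypeMatrix(
        dosages=dos.to_numpy(dtype=float).T,
        markers=markers,
        y=phen.loc[samples].to_numpy(dtype=int),
    )
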