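"""Reference-panel construction: binary marker encoding and LD matrices.

The MHC reference panel is a set of phased haplotypes carrying biallelic
SNPs together with multi-allelic HLA classical alleles and amino-acid
residues.  Multi-allelic variants are recoded as presence/absence
("P"/"A") binary markers — one marker per distinct two-field allele, one
per distinct one-field allele, and one per distinct residue at each
polymorphic amino-acid position — so that the ordinary biallelic LD
machinery (Pearson r between haplotype columns) applies uniformly.

From the binary haplotype matrix this module computes the two correlation
blocks needed for summary-statistics imputation:

* ``sigma_ss`` — correlations among SNP markers (the conditioning set),
* ``sigma_hs`` — cross-correlations of each HLA/amino-acid marker with
  every SNP marker,

and serialises them, with per-marker metadata but **without** any
individual-level haplotypes, into a portable matrix store.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np

logger = logging.getLogger(__name__)

STORE_FORMAT_VERSION = 1

#: fraction of missing haplotype calls above which a marker is dropped
#: rather than correlated pairwise-complete
MAX_MISSING_FRACTION = 0.05

_VALID_BASES = frozenset("ACGT")

_HLA_ALLELE_RE = re.compile(r"^([A-Za-z][A-Za-z0-9]*)\*(\d{1,3})(?::(\d{1,3}))?$")


class PanelError(ValueError):
    """Invalid panel input or construction request."""


class StoreFormatError(IOError):
    """Matrix-store file is unreadable, truncated, or version-incompatible."""


class MarkerKind(str, Enum):
    SNP = "SNP"
    HLA_1FIELD = "HLA_1FIELD"
    HLA_2FIELD = "HLA_2FIELD"
    AA_RESIDUE = "AA_RESIDUE"

    @property
    def is_snp(self) -> bool:
        return self is MarkerKind.SNP


@dataclass(frozen=True)
class Marker:
    """One biallelic marker of the reference panel.

    ``counted_allele`` is the allele whose haplotype code is 1; for
    binarised HLA/amino-acid markers it is the presence symbol ``"P"``
    and ``other_allele`` is ``"A"`` (absence).
    """

    id: str
    kind: MarkerKind
    position: int
    counted_allele: str
    other_allele: str
    frequency: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.frequency <= 1.0):
            raise PanelError(
                f"marker {self.id}: frequency {self.frequency} outside [0, 1]"
            )
        both_bases = (
            self.counted_allele in _VALID_BASES and self.other_allele in _VALID_BASES
        )
        if (self.kind is MarkerKind.SNP) != both_bases:
            raise PanelError(
                f"marker {self.id}: kind {self.kind.value} inconsistent with alleles "
                f"{self.counted_allele}/{self.other_allele} "
                "(SNP iff both alleles are A/C/G/T)"
            )

    @property
    def is_polymorphic(self) -> bool:
        return 0.0 < self.frequency < 1.0


@dataclass
class ReferencePanel:
    """Phased haplotypes over binary markers.

    ``haplotypes`` is an H x M float matrix; entries are 1.0 when the
    haplotype carries the counted allele, 0.0 otherwise, NaN when the
    call is missing.  Marker frequencies are recomputed from the columns
    on construction so the metadata can never drift from the data.
    """

    markers: list[Marker]
    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=float)
        if self.haplotypes.ndim != 2:
            raise PanelError("haplotypes must be a 2-D (H x M) matrix")
        h, m = self.haplotypes.shape
        if m != len(self.markers):
            raise PanelError(
                f"{len(self.markers)} markers but haplotype matrix has {m} columns"
            )
        ids = [mk.id for mk in self.markers]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelError(f"duplicate marker ids in panel: {dupes[:5]}")
        ok = np.isnan(self.haplotypes) | (self.haplotypes == 0) | (self.haplotypes == 1)
        if not ok.all():
            raise PanelError("haplotype entries must be 0, 1, or NaN")
        if h % 2 != 0:
            warnings.warn(
                f"panel has an odd number of haplotypes ({h}); phased diploid "
                "input normally yields an even count",
                stacklevel=2,
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            freqs = np.nanmean(self.haplotypes, axis=0)
        self.markers = [
            dataclasses.replace(mk, frequency=float(f) if np.isfinite(f) else 0.0)
            for mk, f in zip(self.markers, freqs)
        ]

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([mk.frequency for mk in self.markers])

    @classmethod
    def from_columns(cls, columns: Sequence[tuple[Marker, np.ndarray]]) -> "ReferencePanel":
        markers = [mk for mk, _ in columns]
        haps = np.column_stack([np.asarray(c, dtype=float) for _, c in columns])
        return cls(markers=markers, haplotypes=haps)


@dataclass
class MatrixStore:
    """Precomputed LD structure sufficient for imputation.

    Contains only marker metadata and correlation blocks — no
    individual-level haplotypes — so it can be distributed freely.
    """

    snp_markers: list[Marker]
    hla_markers: list[Marker]
    sigma_ss: np.ndarray
    sigma_hs: np.ndarray
    n_haplotypes: int
    region: tuple[str, int, int]

    def __post_init__(self) -> None:
        self.sigma_ss = np.asarray(self.sigma_ss, dtype=float)
        self.sigma_hs = np.asarray(self.sigma_hs, dtype=float)
        s, h = len(self.snp_markers), len(self.hla_markers)
        if self.sigma_ss.shape != (s, s):
            raise PanelError(f"sigma_ss shape {self.sigma_ss.shape} != ({s}, {s})")
        if self.sigma_hs.shape != (h, s):
            raise PanelError(f"sigma_hs shape {self.sigma_hs.shape} != ({h}, {s})")
        if s and not np.allclose(np.diag(self.sigma_ss), 1.0, atol=0):
            raise PanelError("sigma_ss diagonal must be exactly 1")
        if s and np.abs(self.sigma_ss - self.sigma_ss.T).max() > 1e-12:
            raise PanelError("sigma_ss must be symmetric to 1e-12")
        for name, mat in (("sigma_ss", self.sigma_ss), ("sigma_hs", self.sigma_hs)):
            if mat.size and (np.abs(mat) > 1.0).any():
                raise PanelError(f"{name} has entries outside [-1, 1]")

    @property
    def marker_ids(self) -> dict[str, int]:
        """SNP-marker id -> column index in ``sigma_ss``."""
        return {mk.id: i for i, mk in enumerate(self.snp_markers)}


# ---------------------------------------------------------------------------
# Binary encoding of multi-allelic HLA variants
# ---------------------------------------------------------------------------

def parse_hla_allele(token: str) -> tuple[str, str, str | None]:
    """Split ``"DRB1*15:01"`` into ``("DRB1", "15", "01")``.

    One-field names (``"DRB1*15"``) return ``None`` for the second field.
    """
    m = _HLA_ALLELE_RE.match(token.strip())
    if m is None:
        raise PanelError(f"unparseable HLA allele name: {token!r}")
    return m.group(1), m.group(2), m.group(3)


def binarize_hla_alleles(
    calls: Sequence[str | None],
    position: int = 0,
) -> list[tuple[Marker, np.ndarray]]:
    """Encode per-haplotype classical-allele calls at one gene as binary markers.

    Each distinct two-field allele and each distinct one-field allele
    becomes its own presence/absence marker; a two-field call also sets
    its one-field parent marker.  A ``None`` call is missing in every
    derived column.  Monomorphic markers are returned (frequency 0 or 1)
    and excluded later by :func:`build_matrix_store`.

    Returns markers sorted by (one-field first, then allele name).
    """
    parsed: list[tuple[str, str, str | None] | None] = []
    genes = set()
    for c in calls:
        if c is None or (isinstance(c, float) and np.isnan(c)):
            parsed.append(None)
            continue
        gene, f1, f2 = parse_hla_allele(str(c))
        genes.add(gene)
        parsed.append((gene, f1, f2))
    if len(genes) > 1:
        raise PanelError(
            f"calls mix genes {sorted(genes)}; binarize one gene at a time "
            "(phased input provides exactly one call per haplotype per gene)"
        )
    if not genes:
        return []
    gene = genes.pop()

    n = len(calls)
    one_field: dict[str, np.ndarray] = {}
    two_field: dict[str, np.ndarray] = {}
    for i, p in enumerate(parsed):
        if p is None:
            continue
        _, f1, f2 = p
        one_field.setdefault(f1, np.zeros(n))[i] = 1.0
        if f2 is not None:
            two_field.setdefault(f1 + f2, np.zeros(n))[i] = 1.0
    missing = np.array([p is None for p in parsed])

    out: list[tuple[Marker, np.ndarray]] = []
    for fields, col in sorted(one_field.items()) + sorted(two_field.items()):
        col = col.copy()
        col[missing] = np.nan
        kind = MarkerKind.HLA_1FIELD if len(fields) <= 2 else MarkerKind.HLA_2FIELD
        freq = float(np.nanmean(col)) if (~missing).any() else 0.0
        mk = Marker(
            id=f"HLA_{gene}_{fields}",
            kind=kind,
            position=position,
            counted_allele="P",
            other_allele="A",
            frequency=freq,
        )
        out.append((mk, col))
    return out


def binarize_amino_acids(
    residues: Sequence[str | None],
    gene: str,
    aa_position: int | str,
    position: int = 0,
) -> list[tuple[Marker, np.ndarray]]:
    """Encode per-haplotype residues at one amino-acid position as binary markers.

    ``k`` distinct residues yield ``k`` presence/absence markers; a
    position with a single residue is not polymorphic and yields none.
    Indels are treated as one more residue symbol (conventionally ``"-"``
    or ``"del"``).
    """
    n = len(residues)
    cols: dict[str, np.ndarray] = {}
    missing = np.zeros(n, dtype=bool)
    for i, r in enumerate(residues):
        if r is None or (isinstance(r, float) and np.isnan(r)):
            missing[i] = True
            continue
        r = str(r).strip()
        if not r:
            raise PanelError(f"empty residue symbol at index {i}")
        cols.setdefault(r, np.zeros(n))[i] = 1.0
    if len(cols) < 2:
        return []
    out = []
    for res, col in sorted(cols.items()):
        col = col.copy()
        col[missing] = np.nan
        mk = Marker(
            id=f"AA_{gene}_{aa_position}_{res}",
            kind=MarkerKind.AA_RESIDUE,
            position=position,
            counted_allele="P",
            other_allele="A",
            frequency=float(np.nanmean(col)),
        )
        out.append((mk, col))
    return out


# ---------------------------------------------------------------------------
# Correlation matrices
# ---------------------------------------------------------------------------

def _pairwise_corrcoef(columns: np.ndarray) -> np.ndarray:
    """Pearson correlation of columns, pairwise-complete over NaN entries."""
    if not np.isnan(columns).any():
        return np.corrcoef(columns, rowvar=False)
    masked = np.ma.masked_invalid(columns)
    corr = np.ma.corrcoef(masked, rowvar=False)
    return np.asarray(corr.filled(0.0))


def build_matrix_store(
    panel: ReferencePanel,
    maf_min: float = 0.005,
    region: tuple[str, int, int] | None = None,
) -> MatrixStore:
    """Compute the SNP-SNP and HLA-SNP correlation blocks of a panel.

    Markers are retained when their counted-allele frequency lies strictly
    inside ``(maf_min, 1 - maf_min)`` and fewer than
    ``MAX_MISSING_FRACTION`` of their calls are missing.  Correlations are
    Pearson r between binary haplotype columns over all haplotypes
    (pairwise-complete where calls are missing).
    """
    if not panel.markers:
        raise PanelError("empty panel")
    if not (0.0 <= maf_min < 0.5):
        raise PanelError(f"maf_min {maf_min} outside [0, 0.5)")

    freqs = panel.frequencies
    miss = np.isnan(panel.haplotypes).mean(axis=0)
    keep = (freqs > maf_min) & (freqs < 1.0 - maf_min) & (miss < MAX_MISSING_FRACTION)
    n_freq_dropped = int(((freqs <= maf_min) | (freqs >= 1.0 - maf_min)).sum())
    n_miss_dropped = int(keep.size - keep.sum() - 0) - n_freq_dropped
    logger.info(
        "matrix store: retaining %d/%d markers (%d frequency-filtered, %d high-missingness)",
        keep.sum(), keep.size, n_freq_dropped, max(n_miss_dropped, 0),
    )

    kept_idx = np.flatnonzero(keep)
    snp_idx = [i for i in kept_idx if panel.markers[i].kind.is_snp]
    hla_idx = [i for i in kept_idx if not panel.markers[i].kind.is_snp]
    if len(snp_idx) < 2:
        raise PanelError(
            f"only {len(snp_idx)} polymorphic SNP markers retained: "
            "nothing to condition on"
        )

    order = snp_idx + hla_idx
    corr = _pairwise_corrcoef(panel.haplotypes[:, order])
    corr = np.clip(corr, -1.0, 1.0)
    s = len(snp_idx)
    sigma_ss = (corr[:s, :s] + corr[:s, :s].T) / 2.0
    np.fill_diagonal(sigma_ss, 1.0)
    sigma_hs = corr[s:, :s]

    if region is None:
        positions = [panel.markers[i].position for i in order]
        region = ("unknown", min(positions), max(positions))

    return MatrixStore(
        snp_markers=[panel.markers[i] for i in snp_idx],
        hla_markers=[panel.markers[i] for i in hla_idx],
        sigma_ss=sigma_ss,
        sigma_hs=sigma_hs,
        n_haplotypes=panel.n_haplotypes,
        region=region,
    )


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def _write_marker_group(grp: h5py.Group, markers: Sequence[Marker]) -> None:
    str_dt = h5py.string_dtype(encoding="utf-8")
    grp.create_dataset("id", data=[m.id for m in markers], dtype=str_dt)
    grp.create_dataset("kind", data=[m.kind.value for m in markers], dtype=str_dt)
    grp.create_dataset("position", data=np.array([m.position for m in markers], dtype=np.int64))
    grp.create_dataset("counted_allele", data=[m.counted_allele for m in markers], dtype=str_dt)
    grp.create_dataset("other_allele", data=[m.other_allele for m in markers], dtype=str_dt)
    grp.create_dataset("frequency", data=np.array([m.frequency for m in markers], dtype=np.float64))


def _read_marker_group(grp: h5py.Group) -> list[Marker]:
    ids = [s.decode() for s in grp["id"][()]]
    kinds = [s.decode() for s in grp["kind"][()]]
    pos = grp["position"][()]
    ca = [s.decode() for s in grp["counted_allele"][()]]
    oa = [s.decode() for s in grp["other_allele"][()]]
    fr = grp["frequency"][()]
    return [
        Marker(i, MarkerKind(k), int(p), c, o, float(f))
        for i, k, p, c, o, f in zip(ids, kinds, pos, ca, oa, fr)
    ]


def save_store(store: MatrixStore, path: str | Path) -> None:
    """Write a matrix store to a versioned HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "dish-matrix-store"
        f.attrs["format_version"] = STORE_FORMAT_VERSION
        f.attrs["n_haplotypes"] = store.n_haplotypes
        f.attrs["region"] = json.dumps(
            [store.region[0], int(store.region[1]), int(store.region[2])]
        )
        _write_marker_group(f.create_group("snp_markers"), store.snp_markers)
        _write_marker_group(f.create_group("hla_markers"), store.hla_markers)
        f.create_dataset("sigma_ss", data=store.sigma_ss, dtype=np.float64)
        f.create_dataset("sigma_hs", data=store.sigma_hs, dtype=np.float64)


def load_store(path: str | Path) -> MatrixStore:
    """Read a matrix store written by :func:`save_store`."""
    try:
        with h5py.File(path, "r") as f:
            if f.attrs.get("format") != "dish-matrix-store":
                raise StoreFormatError(f"{path}: not a dish matrix store")
            version = int(f.attrs.get("format_version", -1))
            if version != STORE_FORMAT_VERSION:
                raise StoreFormatError(
                    f"{path}: store format version {version} unsupported "
                    f"(expected {STORE_FORMAT_VERSION})"
                )
            chrom, start, end = json.loads(f.attrs["region"])
            return MatrixStore(
                snp_markers=_read_marker_group(f["snp_markers"]),
                hla_markers=_read_marker_group(f["hla_markers"]),
                sigma_ss=f["sigma_ss"][()].reshape(
                    len(f["snp_markers/id"]), len(f["snp_markers/id"])
                ),
                sigma_hs=f["sigma_hs"][()].reshape(
                    len(f["hla_markers/id"]), len(f["snp_markers/id"])
                ),
                n_haplotypes=int(f.attrs["n_haplotypes"]),
                region=(chrom, int(start), int(end)),
            )
    except OSError as exc:
        raise StoreFormatError(f"{path}: unreadable or truncated store ({exc})") from exc


def export_store_tsv(store: MatrixStore, prefix: str | Path) -> list[Path]:
    """Export a store as three audit TSVs: markers, sigma_ss, sigma_hs."""
    import pandas as pd

    prefix = Path(prefix)
    markers = store.snp_markers + store.hla_markers
    mdf = pd.DataFrame(
        {
            "id": [m.id for m in markers],
            "kind": [m.kind.value for m in markers],
            "position": [m.position for m in markers],
            "counted_allele": [m.counted_allele for m in markers],
            "other_allele": [m.other_allele for m in markers],
            "frequency": [m.frequency for m in markers],
        }
    )
    snp_ids = [m.id for m in store.snp_markers]
    hla_ids = [m.id for m in store.hla_markers]
    paths = [
        Path(f"{prefix}.markers.tsv"),
        Path(f"{prefix}.sigma_ss.tsv"),
        Path(f"{prefix}.sigma_hs.tsv"),
    ]
    mdf.to_csv(paths[0], sep="\t", index=False)
    pd.DataFrame(store.sigma_ss, index=snp_ids, columns=snp_ids).to_csv(paths[1], sep="\t")
    pd.DataFrame(store.sigma_hs, index=hla_ids, columns=snp_ids).to_csv(paths[2], sep="\t")
    return paths


# ---------------------------------------------------------------------------
# Haplotype input dialects
# ---------------------------------------------------------------------------

_CALL_ALIASES = {
    "1": 1.0, "P": 1.0, "p": 1.0,
    "0": 0.0, "A": 0.0, "a": 0.0,
    "NA": np.nan, ".": np.nan, "": np.nan, "nan": np.nan,
}


def _infer_kind(marker_id: str) -> MarkerKind | None:
    parts = marker_id.split("_")
    if marker_id.startswith("HLA_") and len(parts) >= 3:
        return MarkerKind.HLA_1FIELD if len(parts[-1]) <= 2 else MarkerKind.HLA_2FIELD
    if marker_id.startswith("AA_") and len(parts) >= 4:
        return MarkerKind.AA_RESIDUE
    return None  # presumably a SNP; needs allele metadata


def read_marker_metadata(path: str | Path) -> dict[str, tuple[int, str, str]]:
    """Read a marker metadata TSV: id, position, counted allele, other allele."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"id", "position", "counted_allele", "other_allele"}
    if not required.issubset(df.columns):
        raise PanelError(
            f"marker metadata {path} missing columns {sorted(required - set(df.columns))}"
        )
    return {
        r.id: (int(r.position), r.counted_allele, r.other_allele)
        for r in df.itertuples()
    }


def read_haplotype_table(
    path: str | Path,
    marker_metadata: dict[str, tuple[int, str, str]] | None = None,
) -> ReferencePanel:
    """Read a phased-haplotype table: one row per marker, one column per haplotype.

    Calls may be ``1``/``0``, ``P``/``A`` (presence/absence aliases), or
    ``NA``/``.`` for missing.  A header row is detected and skipped when
    its non-id fields are not all valid calls.  SNP-marker rows (ids not
    matching the ``HLA_``/``AA_`` naming) require entries in
    ``marker_metadata`` supplying position and alleles.
    """
    marker_metadata = marker_metadata or {}
    rows: list[tuple[Marker, np.ndarray]] = []
    missing_meta: list[str] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise PanelError(f"{path}: empty haplotype table")
    start = 0
    first = lines[0].split("\t")
    # a header row has no valid calls at all; a data row with one bad token
    # should be reported as such, not silently skipped
    if first[1:] and all(tok.strip() not in _CALL_ALIASES for tok in first[1:]):
        start = 1
    if start >= len(lines):
        raise PanelError(f"{path}: no data rows in haplotype table")
    n_cols = None
    for ln in lines[start:]:
        fields = ln.split("\t")
        marker_id, calls = fields[0].strip(), fields[1:]
        if n_cols is None:
            n_cols = len(calls)
        elif len(calls) != n_cols:
            raise PanelError(
                f"{path}: marker {marker_id} has {len(calls)} calls, expected {n_cols}"
            )
        try:
            col = np.array([_CALL_ALIASES[c.strip()] for c in calls])
        except KeyError as exc:
            raise PanelError(
                f"{path}: marker {marker_id}: invalid call {exc.args[0]!r} "
                "(expected 1/0, P/A, or NA)"
            ) from exc
        kind = _infer_kind(marker_id)
        if marker_id in marker_metadata:
            pos, counted, other = marker_metadata[marker_id]
            kind = kind or MarkerKind.SNP
        elif kind is not None:
            pos, counted, other = 0, "P", "A"
        else:
            missing_meta.append(marker_id)
            continue
        freq = float(np.nanmean(col)) if np.isfinite(col).any() else 0.0
        rows.append((Marker(marker_id, kind, pos, counted, other, freq), col))
    if missing_meta:
        raise PanelError(
            f"{path}: SNP markers lack allele/position metadata: "
            f"{missing_meta[:5]}{'...' if len(missing_meta) > 5 else ''} "
            "(provide a marker metadata TSV)"
        )
    return ReferencePanel.from_columns(rows)


def read_phased_vcf(path: str | Path) -> list[tuple[Marker, np.ndarray]]:
    """Read biallelic SNP haplotype columns from a phased VCF.

    The counted allele is ALT.  Genotypes must be phased (``|``
    separator); unphased records are rejected.  Non-SNP and multiallelic
    records are skipped with a log message.
    """
    import pysam

    out: list[tuple[Marker, np.ndarray]] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                skipped += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            if ref not in _VALID_BASES or alt not in _VALID_BASES:
                skipped += 1
                continue
            col = []
            for sample in rec.samples.values():
                if not sample.phased and None not in sample["GT"]:
                    raise PanelError(
                        f"{path}: unphased genotype at {rec.id or rec.pos} "
                        "(phased '|' genotypes required)"
                    )
                for a in sample["GT"]:
                    col.append(np.nan if a is None else float(a))
            col = np.array(col)
            marker_id = rec.id or f"{rec.chrom}:{rec.pos}:{ref}:{alt}"
            freq = float(np.nanmean(col)) if np.isfinite(col).any() else 0.0
            out.append(
                (Marker(marker_id, MarkerKind.SNP, rec.pos, alt, ref, freq), col)
            )
    if skipped:
        logger.info("VCF %s: skipped %d non-SNP/multiallelic records", path, skipped)
    return out
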