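"""Z-score imputation for untyped HLA variants from typed-SNP summary statistics.

Under local LD, association Z scores of variants in a region are jointly
approximately multivariate normal with covariance equal to the LD
correlation matrix.  Writing ``z_typed`` for the observed typed-SNP Z
vector, the conditional expectation of an untyped variant's Z is

    E(z_untyped | z_typed) = sigma_hs (sigma_ss + lambda I)^-1 z_typed

where ``sigma_hs`` holds the untyped variant's correlations with the
typed SNPs and ``sigma_ss`` is the typed-SNP correlation matrix, ridge-
adjusted on the diagonal by ``lambda`` (default 0.15) to damp sampling
noise in the reference correlations and guarantee invertibility.  The
per-variant reliability is the explained variance

    r2pred = sigma^T (sigma_ss + lambda I)^-1 sigma,

conventionally thresholded at 0.5 for reporting.

The module also handles the unglamorous half of the job: reading summary
statistics in common dialects, harmonising effect alleles against the
reference panel (strand complements, sign flips, palindromic-SNP
filtering), and converting extreme Z scores to two-sided P values on a
log-accurate normal tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from .panel import Marker, MatrixStore

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA = 0.15
DEFAULT_R2PRED_MIN = 0.5

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SummaryStatsError(ValueError):
    """Malformed or insufficient summary-statistics input."""


class MatchError(ValueError):
    """No summary records could be aligned to the reference panel."""


class SingularMatrixError(np.linalg.LinAlgError):
    """Typed-SNP correlation matrix is singular (advise lambda > 0)."""


# ---------------------------------------------------------------------------
# Summary statistics input
# ---------------------------------------------------------------------------

_COLUMN_ALIASES = {
    "id": {"snp", "id", "marker", "rsid", "variant_id"},
    "chrom": {"chr", "chrom", "chromosome"},
    "pos": {"bp", "pos", "position", "base_pair_location"},
    "a1": {"a1", "effect_allele", "allele1", "ea"},
    "a2": {"a2", "other_allele", "allele2", "oa", "nea"},
    "z": {"z", "zscore", "z_score", "stat"},
    "beta": {"beta", "b", "effect"},
    "se": {"se", "stderr", "standard_error"},
    "or_": {"or", "odds_ratio"},
    "p": {"p", "pval", "p_value", "pvalue"},
}


def _normalise_columns(df: pd.DataFrame) -> pd.DataFrame:
    mapping = {}
    for col in df.columns:
        key = col.strip().lower()
        for canon, aliases in _COLUMN_ALIASES.items():
            if key in aliases:
                mapping[col] = canon
                break
    return df.rename(columns=mapping)


def read_sumstats(path: str | Path) -> pd.DataFrame:
    """Read a typed-SNP summary-statistics table.

    Recognised columns (case-insensitive): SNP/ID, CHR, BP/POS,
    A1/EFFECT_ALLELE, A2/OTHER_ALLELE, Z, BETA, SE, OR, P.  A signed Z is
    derived when absent: from beta/se, else from OR and P as
    ``sign(log OR) * |Phi^-1(P/2)|``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = _normalise_columns(df)
    missing = [c for c in ("id", "a1", "a2") if c not in df.columns]
    if missing:
        raise SummaryStatsError(
            f"{path}: missing required columns {missing} "
            "(need SNP/ID, A1/EFFECT_ALLELE, A2/OTHER_ALLELE)"
        )
    for col in ("pos", "z", "beta", "se", "or_", "p"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    df["a1"] = df["a1"].str.upper().str.strip()
    df["a2"] = df["a2"].str.upper().str.strip()
    return prepare_sumstats(df)


def prepare_sumstats(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a summary table and fill the ``z`` column from its sources.

    Precedence: an explicit ``z`` column; else ``beta``/``se``; else
    ``or_`` and ``p``.  Records with a non-finite Z, identical alleles,
    or conflicting duplicate entries are dropped with a logged warning.
    """
    df = df.copy()
    if "z" not in df.columns:
        df["z"] = np.nan
    need = df["z"].isna()
    if need.any() and {"beta", "se"}.issubset(df.columns):
        with np.errstate(divide="ignore", invalid="ignore"):
            df.loc[need, "z"] = df.loc[need, "beta"] / df.loc[need, "se"]
        need = df["z"].isna()
    if need.any() and {"or_", "p"}.issubset(df.columns):
        sub = df.loc[need]
        with np.errstate(divide="ignore", invalid="ignore"):
            magnitude = -scipy.stats.norm.ppf(sub["p"].to_numpy() / 2.0)
            sign = np.sign(np.log(sub["or_"].to_numpy()))
        df.loc[need, "z"] = sign * np.abs(magnitude)

    bad_z = ~np.isfinite(df["z"].to_numpy(dtype=float))
    if bad_z.any():
        logger.warning("dropping %d records without a finite Z score", bad_z.sum())
        df = df.loc[~bad_z]
    same = df["a1"] == df["a2"]
    if same.any():
        logger.warning("dropping %d records with identical alleles", same.sum())
        df = df.loc[~same]

    # duplicates: keep exact repeats once, drop conflicting ones entirely
    if df["id"].duplicated().any():
        def _resolve(group: pd.DataFrame) -> pd.DataFrame:
            if len(group) == 1:
                return group
            if group["z"].nunique() == 1 and group["a1"].nunique() == 1:
                return group.iloc[[0]]
            logger.warning(
                "dropping variant %s: duplicated with conflicting records",
                group["id"].iloc[0],
            )
            return group.iloc[0:0]

        df = (
            df.groupby("id", group_keys=False, sort=False)[df.columns]
            .apply(_resolve)
            .reset_index(drop=True)
        )
    if df.empty:
        raise SummaryStatsError("no usable summary-statistics records")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Allele harmonisation
# ---------------------------------------------------------------------------

@dataclass
class MatchedSet:
    """Typed-SNP summary records aligned to panel SNP markers.

    ``panel_idx[i]`` is the column of ``store.sigma_ss`` matched by the
    i-th typed record, and ``z_aligned[i]`` its Z score re-signed to the
    panel's counted allele.  Panel SNPs not in ``panel_idx`` are treated
    as untyped.
    """

    store: MatrixStore
    panel_idx: np.ndarray          # (t,) int — columns of sigma_ss
    z_aligned: np.ndarray          # (t,) float
    sign_flip: np.ndarray          # (t,) int in {+1, -1}
    match_method: list[str]        # "id" or "position"
    typed_ids: list[str]           # summary-record ids, matched order
    unmatched: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)

    @property
    def n_typed(self) -> int:
        return len(self.panel_idx)

    @property
    def untyped_snp_idx(self) -> np.ndarray:
        mask = np.ones(len(self.store.snp_markers), dtype=bool)
        mask[self.panel_idx] = False
        return np.flatnonzero(mask)


def is_strand_ambiguous(a1: str, a2: str) -> bool:
    """A/T and C/G pairs read identically on both strands."""
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def _align(a1: str, a2: str, counted: str, other: str) -> int | None:
    """Sign flip aligning effect allele a1 to the panel's counted allele.

    Returns +1/-1, or None when the allele pairs are irreconcilable even
    after strand complementation.
    """
    if (a1, a2) == (counted, other):
        return 1
    if (a1, a2) == (other, counted):
        return -1
    try:
        c1, c2 = _COMPLEMENT[a1], _COMPLEMENT[a2]
    except KeyError:
        return None
    if (c1, c2) == (counted, other):
        return 1
    if (c1, c2) == (other, counted):
        return -1
    return None


def match_variants(
    sumstats: pd.DataFrame,
    store: MatrixStore,
    allow_position_match: bool = True,
    drop_ambiguous: bool = True,
) -> MatchedSet:
    """Align summary records to panel SNP markers.

    Matching is id-first (marker names are build-agnostic); records still
    unmatched may optionally match by (position, allele pair).  Alleles
    are compared directly and as reverse complements; the Z sign is
    flipped whenever the effect allele aligns to the panel's non-counted
    allele.  Strand-ambiguous (A/T, C/G) SNPs are dropped by default
    because their orientation cannot be verified.
    """
    by_id = {m.id: i for i, m in enumerate(store.snp_markers)}
    by_pos: dict[int, list[int]] = {}
    for i, m in enumerate(store.snp_markers):
        by_pos.setdefault(m.position, []).append(i)

    taken: set[int] = set()
    panel_idx: list[int] = []
    z_aligned: list[float] = []
    flips: list[int] = []
    methods: list[str] = []
    typed_ids: list[str] = []
    unmatched: list[tuple[str, str]] = []

    has_pos = "pos" in sumstats.columns

    for rec in sumstats.itertuples():
        a1, a2, z = rec.a1, rec.a2, float(rec.z)
        if drop_ambiguous and is_strand_ambiguous(a1, a2):
            unmatched.append((rec.id, "strand_ambiguous"))
            continue

        idx, method = None, None
        if rec.id in by_id:
            idx, method = by_id[rec.id], "id"
        elif allow_position_match and has_pos and not pd.isna(rec.pos):
            for cand in by_pos.get(int(rec.pos), []):
                m = store.snp_markers[cand]
                if _align(a1, a2, m.counted_allele, m.other_allele) is not None:
                    idx, method = cand, "position"
                    break
        if idx is None:
            unmatched.append((rec.id, "not_in_panel"))
            continue
        if idx in taken:
            unmatched.append((rec.id, "panel_snp_already_matched"))
            continue

        m = store.snp_markers[idx]
        flip = _align(a1, a2, m.counted_allele, m.other_allele)
        if flip is None:
            unmatched.append((rec.id, "allele_mismatch"))
            continue

        taken.add(idx)
        panel_idx.append(idx)
        z_aligned.append(flip * z)
        flips.append(flip)
        methods.append(method)
        typed_ids.append(rec.id)

    if not panel_idx:
        raise MatchError(
            "no summary records matched the panel (check ids, positions, "
            "and that both inputs cover the same region)"
        )
    logger.info(
        "matched %d typed SNPs (%d by id, %d by position); %d records unmatched",
        len(panel_idx),
        sum(m == "id" for m in methods),
        sum(m == "position" for m in methods),
        len(unmatched),
    )
    return MatchedSet(
        store=store,
        panel_idx=np.array(panel_idx, dtype=int),
        z_aligned=np.array(z_aligned, dtype=float),
        sign_flip=np.array(flips, dtype=int),
        match_method=methods,
        typed_ids=typed_ids,
        unmatched=unmatched,
    )


# ---------------------------------------------------------------------------
# The conditional-expectation core
# ---------------------------------------------------------------------------

def regularize(sigma_ss_typed: np.ndarray, lam: float) -> np.ndarray:
    """Ridge-adjust a correlation matrix: return ``sigma + lam * I``."""
    sigma = np.asarray(sigma_ss_typed, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {sigma.shape}")
    if sigma.size and np.abs(sigma - sigma.T).max() > 1e-8:
        raise ValueError("correlation matrix is not symmetric")
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    return sigma + lam * np.eye(sigma.shape[0])


def impute_z(
    z_typed: np.ndarray,
    sigma_hs_typed: np.ndarray,
    sigma_ss_typed: np.ndarray,
    lam: float = DEFAULT_LAMBDA,
) -> tuple[np.ndarray, np.ndarray]:
    """Impute Z scores and r2pred for untyped variants.

    Parameters
    ----------
    z_typed : (t,) array
        Sign-aligned Z scores of the typed SNPs.
    sigma_hs_typed : (u, t) array
        Correlation of each untyped variant (rows) with the typed SNPs.
    sigma_ss_typed : (t, t) array
        Correlation matrix of the typed SNPs.
    lam : float
        Ridge constant added to the diagonal.

    Returns
    -------
    (z_imp, r2pred) : ((u,), (u,)) arrays
        ``z_imp = sigma_hs (sigma_ss + lam I)^-1 z_typed`` and
        ``r2pred[i] = sigma_i^T (sigma_ss + lam I)^-1 sigma_i``, computed
        with a Cholesky solve — the matrix is never explicitly inverted.
    """
    z_typed = np.atleast_1d(np.asarray(z_typed, dtype=float))
    sigma_hs_typed = np.atleast_2d(np.asarray(sigma_hs_typed, dtype=float))
    sigma_ss_typed = np.atleast_2d(np.asarray(sigma_ss_typed, dtype=float))
    for name, arr in (
        ("z_typed", z_typed),
        ("sigma_hs_typed", sigma_hs_typed),
        ("sigma_ss_typed", sigma_ss_typed),
    ):
        if not np.isfinite(arr).all():
            raise ValueError(f"NaN/inf in {name}")
    t = z_typed.shape[0]
    if sigma_ss_typed.shape != (t, t) or sigma_hs_typed.shape[1] != t:
        raise ValueError(
            f"inconsistent shapes: z {z_typed.shape}, "
            f"sigma_hs {sigma_hs_typed.shape}, sigma_ss {sigma_ss_typed.shape}"
        )

    a = regularize(sigma_ss_typed, lam)
    try:
        cho = scipy.linalg.cho_factor(a, lower=True)
    except scipy.linalg.LinAlgError as exc:
        if lam == 0:
            raise SingularMatrixError(
                "typed-SNP correlation matrix is singular with lambda=0; "
                "rerun with lambda > 0 (default 0.15)"
            ) from exc
        raise
    # weights^T, shape (t, u): column i solves (sigma_ss + lam I) w = sigma_i
    wt = scipy.linalg.cho_solve(cho, sigma_hs_typed.T)
    z_imp = wt.T @ z_typed
    r2pred = np.einsum("ut,tu->u", sigma_hs_typed, wt)
    return z_imp, np.clip(r2pred, 0.0, None)


def z_to_p(z: float | np.ndarray) -> float | np.ndarray:
    """Two-sided standard-normal P value, ``2 * Phi(-|z|)``.

    Uses the complementary-error-function tail, which stays accurate in
    the extreme tail where a naive ``1 - CDF`` underflows to zero.
    Beyond the float64 range (|z| > ~38.5, P < ~1e-308) the value is
    reconstructed from the log tail in extended precision, so P stays
    strictly positive out to |z| >= 41 (P ~ 1e-368).
    """
    z = np.asarray(z, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("Z must be finite")
    p = 2.0 * scipy.stats.norm.sf(np.abs(z))
    tiny = p < 1e-300
    if not np.any(tiny):
        return float(p) if p.ndim == 0 else p
    logp = scipy.stats.norm.logsf(np.abs(z)) + np.log(2.0)
    p_ext = np.exp(np.asarray(logp, dtype=np.longdouble))
    if p.ndim == 0:
        return p_ext[()]
    out = p.astype(np.longdouble)
    out[tiny] = np.atleast_1d(p_ext)[tiny]
    return out


def z_to_neglog10_p(z: float | np.ndarray) -> float | np.ndarray:
    """-log10 of the two-sided P, exact even beyond float underflow."""
    z = np.asarray(z, dtype=float)
    logp = scipy.stats.norm.logsf(np.abs(z)) + np.log(2.0)
    out = -logp / np.log(10.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# End-to-end run
# ---------------------------------------------------------------------------

STATUS_TYPED = "typed"
STATUS_IMPUTED = "imputed"
STATUS_LOW_R2PRED = "low_r2pred"

RESULT_COLUMNS = ["id", "kind", "pos", "z", "p", "r2pred", "n_typed", "status", "lambda_used"]


def run_dish(
    sumstats: pd.DataFrame,
    store: MatrixStore,
    lam: float = DEFAULT_LAMBDA,
    r2pred_min: float = DEFAULT_R2PRED_MIN,
    impute_snps: bool = False,
    allow_position_match: bool = True,
    drop_ambiguous: bool = True,
) -> pd.DataFrame:
    """Impute Z, P and r2pred for every untyped panel variant.

    All matched typed SNPs in the region form a single conditioning set.
    Every HLA/amino-acid marker is imputed; unmatched panel SNPs are
    imputed too when ``impute_snps``.  Typed SNPs keep their observed Z
    (r2pred recorded as 1).  Rows with ``r2pred < r2pred_min`` are
    flagged ``low_r2pred``, not removed.  Output is sorted by position.
    """
    matched = match_variants(
        sumstats,
        store,
        allow_position_match=allow_position_match,
        drop_ambiguous=drop_ambiguous,
    )
    return run_dish_matched(
        matched, lam=lam, r2pred_min=r2pred_min, impute_snps=impute_snps
    )


def run_dish_matched(
    matched: MatchedSet,
    lam: float = DEFAULT_LAMBDA,
    r2pred_min: float = DEFAULT_R2PRED_MIN,
    impute_snps: bool = False,
) -> pd.DataFrame:
    """As :func:`run_dish`, starting from an already-aligned MatchedSet."""
    store = matched.store
    t_idx = matched.panel_idx
    n_typed = matched.n_typed

    untyped_markers: list[Marker] = list(store.hla_markers)
    sigma_blocks = [store.sigma_hs[:, t_idx]]
    if impute_snps:
        u_idx = matched.untyped_snp_idx
        untyped_markers += [store.snp_markers[i] for i in u_idx]
        sigma_blocks.append(store.sigma_ss[np.ix_(u_idx, t_idx)])
    sigma_hs_typed = (
        np.vstack(sigma_blocks) if untyped_markers else np.empty((0, n_typed))
    )

    sigma_ss_typed = store.sigma_ss[np.ix_(t_idx, t_idx)]
    z_imp, r2pred = impute_z(matched.z_aligned, sigma_hs_typed, sigma_ss_typed, lam)

    rows: list[dict] = []
    for mk, z, r2 in zip(untyped_markers, z_imp, r2pred):
        rows.append(
            {
                "id": mk.id,
                "kind": mk.kind.value,
                "pos": mk.position,
                "z": z,
                "p": z_to_p(z),
                "r2pred": min(float(r2), 1.0) if r2 <= 1.0 + 1e-8 else float(r2),
                "n_typed": n_typed,
                "status": STATUS_IMPUTED if r2 >= r2pred_min else STATUS_LOW_R2PRED,
                "lambda_used": lam,
            }
        )
    for i, idx in enumerate(t_idx):
        mk = store.snp_markers[idx]
        z = matched.z_aligned[i]
        rows.append(
            {
                "id": mk.id,
                "kind": mk.kind.value,
                "pos": mk.position,
                "z": z,
                "p": z_to_p(z),
                "r2pred": 1.0,
                "n_typed": n_typed,
                "status": STATUS_TYPED,
                "lambda_used": lam,
            }
        )

    logger.info(
        "run: %d typed, %d dropped/unmatched, %d imputed, lambda=%g",
        n_typed, len(matched.unmatched), len(untyped_markers), lam,
    )
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return out.sort_values(["pos", "id"], kind="stable").reset_index(drop=True)


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write an imputation-result table as TSV."""
    results.to_csv(path, sep="\t", index=False, float_format="%.6g")
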