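"""Marker quality control, in-silico hybrid synthesis, and genomic relationship matrices.

Parental inbred lines are genotyped; single-cross (F1) hybrid genotypes are
reconstructed deterministically from their parents, so only the inbreds need to
be assayed.  Additive kinship follows VanRaden's centered-dosage formulation

    G_a = W_A W_A' / (2 * sum_i p_i (1 - p_i)),      w_ij = x_ij - 2 p_i,

and dominance kinship follows Vitezica's orthogonal parameterisation with codes
-2q^2 / 2pq / -2p^2 for dosages 0/1/2 and denominator 4 * sum_i (p_i q_i)^2.
Allele frequencies are computed on the hybrid panel (the prediction targets),
not on the parents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "AlleleStats",
    "GenomicRelationship",
    "qc_markers",
    "synthesize_hybrids",
    "allele_stats",
    "additive_grm",
    "dominance_grm",
    "read_marker_table",
    "read_vcf_dosages",
    "read_cross_plan",
]

ROLES = ("parent", "hybrid", "check")


@dataclass
class MarkerMatrix:
    """Individuals x markers dosage matrix (0/1/2, NaN = missing)."""

    individual_ids: list[str]
    marker_ids: list[str]
    dosage: np.ndarray  # float array, NaN for missing
    role: list[str]
    qc_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.individual_ids), len(self.marker_ids)):
            raise ValueError("dosage shape does not match id lists")
        if len(self.role) != len(self.individual_ids):
            raise ValueError("one role per individual required")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicate individual ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids")
        bad = set(self.role) - set(ROLES)
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def index_of(self, individual_id: str) -> int:
        return self.individual_ids.index(individual_id)

    def subset_individuals(self, ids: list[str]) -> "MarkerMatrix":
        idx = [self.individual_ids.index(i) for i in ids]
        return MarkerMatrix(
            individual_ids=list(ids),
            marker_ids=list(self.marker_ids),
            dosage=self.dosage[idx, :].copy(),
            role=[self.role[i] for i in idx],
            qc_log=list(self.qc_log),
        )

    def ids_with_role(self, role: str) -> list[str]:
        return [i for i, r in zip(self.individual_ids, self.role) if r == role]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.individual_ids, columns=self.marker_ids)


@dataclass
class AlleleStats:
    """Per-marker allele frequency p, call rate, and MAF over a chosen panel."""

    marker_ids: list[str]
    p: np.ndarray          # frequency of the counted allele; NaN if undefined
    call_rate: np.ndarray

    @property
    def maf(self) -> np.ndarray:
        return np.minimum(self.p, 1.0 - self.p)


@dataclass
class GenomicRelationship:
    individual_ids: list[str]
    matrix: np.ndarray
    effect_kind: str  # "additive" | "dominance"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.individual_ids),) * 2:
            raise ValueError("matrix dimension must equal number of individuals")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")
        self.matrix = (m + m.T) / 2.0
        w = np.linalg.eigvalsh(self.matrix)
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise ValueError(f"relationship matrix not PSD (min eigenvalue {w.min():.3g})")


def _het_in_parents(m: MarkerMatrix) -> np.ndarray:
    """Boolean mask of markers heterozygous in at least one parental line."""
    rows = [i for i, r in enumerate(m.role) if r == "parent"]
    if not rows:
        return np.zeros(m.n_markers, dtype=bool)
    d = m.dosage[rows, :]
    return np.nansum(d == 1.0, axis=0) > 0


def _monomorphic(d: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        mn = np.nanmin(d, axis=0)
        mx = np.nanmax(d, axis=0)
    all_missing = np.isnan(d).all(axis=0)
    return (mn == mx) | all_missing


def qc_markers(
    m: MarkerMatrix,
    max_missing_rate: float = 0.05,
    min_maf: float = 0.05,
    drop_het_parents: bool = True,
    maf_panel: list[str] | None = None,
) -> MarkerMatrix:
    """Filter markers by call rate, parental heterozygosity, polymorphism and MAF.

    Rules are applied in that fixed order and each step's removal count is
    appended to ``qc_log``.  A marker survives the call-rate rule only if its
    call rate strictly exceeds ``1 - max_missing_rate`` (the removal rule is
    "call rate <= threshold"), and survives the MAF rule only if MAF strictly
    exceeds ``min_maf``.  ``maf_panel`` selects the individuals on which allele
    frequencies are computed (default: hybrids if present, else everyone).
    """
    if m.n_markers == 0:
        raise ValueError("empty marker matrix")
    for name, v in (("max_missing_rate", max_missing_rate), ("min_maf", min_maf)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")

    keep = np.ones(m.n_markers, dtype=bool)
    log: list[str] = []

    call_rate = 1.0 - np.isnan(m.dosage).mean(axis=0)
    drop = keep & (call_rate <= 1.0 - max_missing_rate)
    log.append(f"call_rate: removed {int(drop.sum())}")
    keep &= ~drop

    if drop_het_parents:
        drop = keep & _het_in_parents(m)
        log.append(f"het_parents: removed {int(drop.sum())}")
        keep &= ~drop

    drop = keep & _monomorphic(m.dosage)
    log.append(f"monomorphic: removed {int(drop.sum())}")
    keep &= ~drop

    if min_maf > 0:
        if maf_panel is None:
            hybrids = m.ids_with_role("hybrid")
            maf_panel = hybrids if hybrids else list(m.individual_ids)
        rows = [m.individual_ids.index(i) for i in maf_panel]
        d = m.dosage[rows, :]
        with np.errstate(invalid="ignore"):
            p = np.nanmean(d, axis=0) / 2.0
        maf = np.minimum(p, 1.0 - p)
        drop = keep & ~(maf > min_maf)
        log.append(f"maf: removed {int(drop.sum())}")
        keep &= ~drop

    if not keep.any():
        raise ValueError("empty after QC: all markers removed")
    cols = np.flatnonzero(keep)
    return MarkerMatrix(
        individual_ids=list(m.individual_ids),
        marker_ids=[m.marker_ids[j] for j in cols],
        dosage=m.dosage[:, cols].copy(),
        role=list(m.role),
        qc_log=m.qc_log + log,
    )


def synthesize_hybrids(
    parents: MarkerMatrix,
    cross_plan: list[tuple[str, str, str]],
) -> MarkerMatrix:
    """Build F1 hybrid dosages as the mean of the two (homozygous) parent dosages.

    0x0 -> 0, 2x2 -> 2, 0x2 -> 1; missing in either parent propagates to the
    hybrid.  A dosage-1 (heterozygous) parent at a retained marker is an error:
    the F1 genotype of an inbred cross is only determined for homozygous loci.
    """
    out_rows = []
    for mother, father, hybrid in cross_plan:
        dm = parents.dosage[parents.index_of(mother), :]
        df = parents.dosage[parents.index_of(father), :]
        for pid, d in ((mother, dm), (father, df)):
            het = np.flatnonzero(d == 1.0)
            if het.size:
                raise ValueError(
                    f"parent {pid} heterozygous at marker {parents.marker_ids[het[0]]}"
                )
        out_rows.append((dm + df) / 2.0)
    hybrid_ids = [h for _, _, h in cross_plan]
    return MarkerMatrix(
        individual_ids=hybrid_ids,
        marker_ids=list(parents.marker_ids),
        dosage=np.vstack(out_rows) if out_rows else np.empty((0, parents.n_markers)),
        role=["hybrid"] * len(hybrid_ids),
        qc_log=list(parents.qc_log),
    )


def allele_stats(m: MarkerMatrix, subset: list[str] | None = None) -> AlleleStats:
    """Allele frequency p = mean dosage / 2 and call rate, over ``subset``."""
    if subset is None:
        subset = list(m.individual_ids)
    if not subset:
        raise ValueError("subset must be non-empty")
    rows = [m.individual_ids.index(i) for i in subset]
    d = m.dosage[rows, :]
    call_rate = 1.0 - np.isnan(d).mean(axis=0)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(d, axis=0) / 2.0  # NaN (undefined) when all entries missing
    return AlleleStats(marker_ids=list(m.marker_ids), p=p, call_rate=call_rate)


def _checked_frequencies(m: MarkerMatrix, stats: AlleleStats) -> np.ndarray:
    if stats.marker_ids != m.marker_ids:
        raise ValueError("allele stats do not match marker matrix")
    p = np.asarray(stats.p, dtype=float)
    if np.isnan(p).any():
        raise ValueError("undefined allele frequency (all-missing marker)")
    return p


def additive_grm(
    m: MarkerMatrix,
    stats: AlleleStats,
    center: bool = True,
) -> GenomicRelationship:
    """VanRaden additive GRM; missing dosages are imputed to their expectation 2p.

    ``center=False`` uses the raw 0/1/2 coding in the cross-product (same
    denominator); the centered form is the default because only it yields the
    mean-diagonal ~ 1 + f calibration of a relationship matrix.
    """
    p = _checked_frequencies(m, stats)
    pq = p * (1.0 - p)
    denom = 2.0 * pq.sum()
    if denom <= 0:
        raise ValueError("all markers monomorphic: additive GRM denominator is zero")
    x = m.dosage.copy()
    miss = np.isnan(x)
    if miss.any():
        x[miss] = np.broadcast_to(2.0 * p, x.shape)[miss]
    w = x - 2.0 * p if center else x
    g = (w @ w.T) / denom
    return GenomicRelationship(list(m.individual_ids), g, "additive")


def dominance_grm(m: MarkerMatrix, stats: AlleleStats) -> GenomicRelationship:
    """Vitezica dominance GRM with codes -2q^2 / 2pq / -2p^2 for dosage 0/1/2."""
    p = _checked_frequencies(m, stats)
    q = 1.0 - p
    denom = 4.0 * ((p * q) ** 2).sum()
    if denom <= 0:
        raise ValueError("all markers monomorphic: dominance GRM denominator is zero")
    x = m.dosage
    codes = {0.0: -2.0 * q**2, 1.0: 2.0 * p * q, 2.0: -2.0 * p**2}
    w = np.empty_like(x)
    for dose, code in codes.items():
        mask = x == dose
        w[mask] = np.broadcast_to(code, x.shape)[mask]
    miss = np.isnan(x)
    if miss.any():
        # expectation of the dominance code under HWE is 0
        w[miss] = 0.0
    g = (w @ w.T) / denom
    return GenomicRelationship(list(m.individual_ids), g, "dominance")


# ---------------------------------------------------------------------------
# file round-trips

def read_marker_table(path, role: str | list[str] = "parent") -> MarkerMatrix:
    """Read a dosage table: rows = individuals (index), columns = markers, NA allowed."""
    df = pd.read_csv(path, index_col=0)
    roles = [role] * len(df) if isinstance(role, str) else list(role)
    return MarkerMatrix(
        individual_ids=[str(i) for i in df.index],
        marker_ids=[str(c) for c in df.columns],
        dosage=df.to_numpy(dtype=float),
        role=roles,
    )


def read_vcf_dosages(path, role: str = "parent") -> MarkerMatrix:
    """Read diploid GT dosages from an (uncompressed) VCF file.

    The dosage counts ALT alleles; missing genotypes ('./.' or '.') become NaN.
    Phased separators are accepted.
    """
    ids: list[str] = []
    marker_ids: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                ids = fields[9:]
                continue
            chrom, pos, vid = fields[0], fields[1], fields[2]
            marker_ids.append(vid if vid not in (".", "") else f"{chrom}_{pos}")
            fmt = fields[8].split(":")
            gt_idx = fmt.index("GT")
            row = []
            for sample in fields[9:]:
                gt = sample.split(":")[gt_idx].replace("|", "/")
                alleles = gt.split("/")
                if "." in alleles or gt == ".":
                    row.append(np.nan)
                else:
                    row.append(float(sum(int(a) > 0 for a in alleles)))
            rows.append(row)
    dosage = np.array(rows, dtype=float).T if rows else np.empty((len(ids), 0))
    return MarkerMatrix(ids, marker_ids, dosage, [role] * len(ids))


def read_cross_plan(path) -> list[tuple[str, str, str]]:
    """Read a 3-column CSV (mother, father, hybrid)."""
    df = pd.read_csv(path)
    if df.shape[1] < 3:
        raise ValueError("cross plan needs 3 columns: mother, father, hybrid")
    return [tuple(map(str, row[:3])) for row in df.itertuples(index=False)]
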