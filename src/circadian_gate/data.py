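"""Study design, expression matrices, gene identifiers and triad tables.

The experimental layout modelled here is a two-condition circadian time
course: seedlings under free-running conditions receive identical acute
(3 h) cold treatments ending at six zeitgeber times (ZT28..ZT48, every
4 h), with contemporaneous control samples and three biological
replicates per condition x timepoint — 36 RNA-seq samples in total.
Every matrix in the pipeline is indexed by this design.

Gene identifiers follow the IWGSC RefSeq convention for hexaploid bread
wheat (e.g. ``TraesCS1A02G123456``): the two characters after ``TraesCS``
encode the chromosome (1-7) and subgenome (A, B or D); ``U`` marks
unplaced genes. Homoeologous gene copies on the three subgenomes are
organised into 1:1:1 triads.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTROL = "control"
COLD = "cold"
DEFAULT_TIMEPOINTS = (28, 32, 36, 40, 44, 48)

#: Hours between subjective dawn (ZT24 under free run) and clock zero.
DAWN_ZT = 24.0

_GENE_ID_RE = re.compile(r"^TraesCS([1-7])([ABD])\d{2}G\d+")
_GENE_ID_U_RE = re.compile(r"^TraesCSU\d{2}G\d+")


def zt_to_phase(zt):
    """Map a zeitgeber time to hours after subjective dawn, in [0, 24)."""
    return np.asarray(zt, dtype=float) % 24.0 if np.ndim(zt) else float(zt) % 24.0


def circular_distance_h(a, b, period: float = 24.0):
    """Shortest distance between two clock times on a circle of given period."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % period
    return np.minimum(d, period - d)


def nearest_timepoint(phase: float, timepoints=DEFAULT_TIMEPOINTS) -> int:
    """Sampled ZT whose circadian phase is closest (circularly) to ``phase``.

    Ties are broken toward the earlier timepoint so the mapping is
    deterministic.
    """
    tps = np.asarray(sorted(timepoints))
    d = circular_distance_h(zt_to_phase(tps), phase % 24.0)
    return int(tps[int(np.argmin(d))])


@dataclass(frozen=True)
class GeneID:
    """Parsed wheat gene identifier.

    ``subgenome`` is one of ``A``/``B``/``D`` for placed genes, ``U`` for
    unplaced, or ``None`` when the identifier does not match the
    ``TraesCS`` pattern (such genes are retained for expression and
    gating analyses but excluded from subgenome/triad summaries).
    """

    raw: str
    chromosome: str | None = None
    subgenome: str | None = None

    @property
    def parseable(self) -> bool:
        return self.subgenome is not None


def parse_gene_id(raw: str) -> GeneID:
    """Extract chromosome and subgenome from a TraesCS-style identifier."""
    m = _GENE_ID_RE.match(raw)
    if m:
        return GeneID(raw=raw, chromosome=m.group(1), subgenome=m.group(2))
    if _GENE_ID_U_RE.match(raw):
        return GeneID(raw=raw, chromosome="U", subgenome="U")
    return GeneID(raw=raw)


def subgenome_of(raw: str) -> str | None:
    return parse_gene_id(raw).subgenome


@dataclass
class StudyDesign:
    """Sample sheet for the two-condition circadian time course.

    Parameters
    ----------
    samples
        DataFrame indexed by sample id with columns ``timepoint_zt``
        (int hours), ``condition`` (``control``/``cold``) and
        ``replicate`` (int, 1-based).
    treatment_duration
        Length in hours of each acute cold treatment; a sample's ZT
        label marks the END of its treatment window, and control
        samples at the same ZT are contemporaneous.
    """

    samples: pd.DataFrame
    treatment_duration: float = 3.0

    def __post_init__(self) -> None:
        required = {"timepoint_zt", "condition", "replicate"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValueError(f"design is missing columns: {sorted(missing)}")
        if self.samples.index.duplicated().any():
            raise ValueError("duplicate sample ids in design")
        bad = set(self.samples["condition"]) - {CONTROL, COLD}
        if bad:
            raise ValueError(f"unknown conditions in design: {sorted(bad)}")
        tps = self.timepoints
        if len(tps) < 2:
            raise ValueError("design needs at least 2 timepoints for delta profiles")
        diffs = np.diff(tps)
        if not (diffs > 0).all():
            raise ValueError("timepoints must be strictly increasing")
        if not np.allclose(diffs, diffs[0]):
            raise ValueError("timepoints must be evenly spaced")
        cell_sizes = self.samples.groupby(
            ["condition", "timepoint_zt"], observed=True
        ).size()
        expected_cells = len(tps) * len(self.conditions)
        if len(cell_sizes) < expected_cells:
            raise ValueError("every condition x timepoint cell needs >=1 replicate")
        if len(tps) != 6:
            warnings.warn(
                f"design has {len(tps)} timepoints; ETMR binning assumes six "
                "4 h-spaced timepoints spanning a 24 h cycle",
                stacklevel=2,
            )

    @property
    def timepoints(self) -> list[int]:
        return sorted(int(t) for t in self.samples["timepoint_zt"].unique())

    @property
    def conditions(self) -> list[str]:
        order = [CONTROL, COLD]
        present = set(self.samples["condition"])
        return [c for c in order if c in present]

    @property
    def sampling_interval(self) -> float:
        return float(np.diff(self.timepoints)[0])

    @property
    def n_replicates(self) -> int:
        """Smallest condition x timepoint group size."""
        return int(
            self.samples.groupby(["condition", "timepoint_zt"], observed=True)
            .size()
            .min()
        )

    def sample_ids(self, condition: str | None = None, zt: int | None = None) -> list[str]:
        mask = pd.Series(True, index=self.samples.index)
        if condition is not None:
            mask &= self.samples["condition"] == condition
        if zt is not None:
            mask &= self.samples["timepoint_zt"] == zt
        return list(self.samples.index[mask])

    @classmethod
    def standard(cls, n_replicates: int = 3, timepoints=DEFAULT_TIMEPOINTS) -> "StudyDesign":
        """The 36-sample layout: 6 ZTs x {control, cold} x replicates."""
        rows = []
        for cond in (CONTROL, COLD):
            for zt in timepoints:
                for rep in range(1, n_replicates + 1):
                    rows.append((f"{cond}_ZT{zt}_r{rep}", zt, cond, rep))
        df = pd.DataFrame(
            rows, columns=["sample_id", "timepoint_zt", "condition", "replicate"]
        ).set_index("sample_id")
        return cls(samples=df)

    def to_frame(self) -> pd.DataFrame:
        return self.samples.reset_index().rename(columns={"index": "sample_id"})


# ---------------------------------------------------------------------------
# I/O


def _sep_for(path, dialect: str | None) -> str:
    if dialect is not None:
        return {"tsv": "\t", "csv": ","}[dialect]
    return "," if str(path).endswith(".csv") else "\t"


def load_design(path, dialect: str | None = None) -> StudyDesign:
    df = pd.read_csv(path, sep=_sep_for(path, dialect))
    return StudyDesign(samples=df.set_index("sample_id"))


def write_design(design: StudyDesign, path, dialect: str | None = None) -> None:
    design.to_frame().to_csv(path, sep=_sep_for(path, dialect), index=False)


def load_counts(path, design_path, dialect: str | None = None):
    """Read a gene x sample count matrix and its design; validate both.

    Returns ``(counts, design)`` where ``counts`` is a DataFrame with
    gene ids as index and the design's sample ids as columns.
    """
    design = load_design(design_path, dialect)
    counts = pd.read_csv(path, sep=_sep_for(path, dialect), index_col=0)
    return validate_counts(counts, design), design


def validate_counts(counts: pd.DataFrame, design: StudyDesign) -> pd.DataFrame:
    if counts.index.duplicated().any():
        dups = counts.index[counts.index.duplicated()].unique()[:5]
        raise ValueError(f"duplicate gene ids in counts: {list(dups)}")
    unknown = set(counts.columns) - set(design.samples.index)
    if unknown:
        raise ValueError(f"samples in counts missing from design: {sorted(unknown)}")
    missing = set(design.samples.index) - set(counts.columns)
    if missing:
        raise ValueError(f"design samples missing from counts: {sorted(missing)}")
    vals = counts.to_numpy()
    if not np.isfinite(vals).all():
        raise ValueError("counts contain non-finite values")
    if (vals < 0).any():
        raise ValueError("counts contain negative values")
    # column order follows the design for positional auditability
    out = counts.loc[:, list(design.samples.index)]
    out.columns.name = design.samples.index.name
    out.index.name = "gene_id"
    return out


def write_counts(counts: pd.DataFrame, path, dialect: str | None = None) -> None:
    counts.to_csv(path, sep=_sep_for(path, dialect), index_label="gene_id")


def load_counts_xlsx(path, sheet=0, design: StudyDesign | None = None) -> pd.DataFrame:
    """Read a gene-count workbook (first column gene ids, one column per sample)."""
    counts = pd.read_excel(path, sheet_name=sheet, index_col=0)
    if design is not None:
        counts = validate_counts(counts, design)
    return counts


TRIAD_COLUMNS = ["triad_id", "gene_A", "gene_B", "gene_D"]


def load_triads(path, dialect: str | None = "csv") -> pd.DataFrame:
    """Read and validate a 1:1:1 homoeolog triad table.

    Rows whose three members do not parse to exactly the subgenome set
    {A, B, D} are dropped (with a logged count). A gene appearing in
    more than one retained triad is an error.
    """
    df = pd.read_csv(path, sep=_sep_for(path, dialect))
    if df.empty:
        warnings.warn("triad table is empty", stacklevel=2)
        return pd.DataFrame(columns=TRIAD_COLUMNS)
    df = df.rename(columns=dict(zip(df.columns[:4], TRIAD_COLUMNS)))[TRIAD_COLUMNS]
    return validate_triads(df)


def validate_triads(df: pd.DataFrame) -> pd.DataFrame:
    if df.empty:
        return df.reindex(columns=TRIAD_COLUMNS)
    keep = []
    for _, row in df.iterrows():
        subs = {
            subgenome_of(str(row["gene_A"])),
            subgenome_of(str(row["gene_B"])),
            subgenome_of(str(row["gene_D"])),
        }
        # members must cover A, B and D exactly once each, in column order
        ok = (
            subgenome_of(str(row["gene_A"])) == "A"
            and subgenome_of(str(row["gene_B"])) == "B"
            and subgenome_of(str(row["gene_D"])) == "D"
            and subs == {"A", "B", "D"}
        )
        keep.append(ok)
    dropped = int(len(keep) - sum(keep))
    if dropped:
        logger.warning("dropped %d triad rows whose members are not 1:1:1 A/B/D", dropped)
    out = df.loc[keep].reset_index(drop=True)
    genes = pd.concat([out["gene_A"], out["gene_B"], out["gene_D"]])
    if genes.duplicated().any():
        dup = genes[genes.duplicated()].iloc[0]
        raise ValueError(f"gene {dup!r} appears in more than one triad")
    return out


def write_triads(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
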