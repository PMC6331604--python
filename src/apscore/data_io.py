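"""Readers and writers for the TSV/GMT formats used throughout the pipeline.

All tabular formats are plain TSV, UTF-8, no quoting, with the literal token
``NA`` for missing values.  Gene identity is the symbol string, case-sensitive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NA_TOKEN = "NA"

TISSUE_GROUPS = ("NT", "LGG", "GBM")
GENDERS = ("F", "M")
GRADES = ("II", "III", "IV")
IDH_LEVELS = ("mutant", "wildtype")
MGMT_LEVELS = ("methylated", "unmethylated")
SUBTYPES = ("CL", "NE", "ME", "PN")
YESNO = ("yes", "no")

CLINICAL_COLUMNS = (
    "sample_id",
    "tissue_group",
    "os_days",
    "event",
    "age",
    "gender",
    "grade",
    "idh",
    "mgmt",
    "subtype",
    "chemo",
    "radio",
)


class DataIOError(ValueError):
    """Raised on malformed or invalid input files."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise DataIOError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Log2-scale gene-by-sample expression matrix."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataIOError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            raise DataIOError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise DataIOError(f"unknown sample ids: {missing[:5]}")
        cols = [idx[s] for s in sample_ids]
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids), self.values[:, cols])

    def gene_values(self, gene: str) -> np.ndarray:
        try:
            i = self.gene_ids.index(gene)
        except ValueError:
            raise DataIOError(f"unknown gene id: {gene!r}") from None
        return self.values[i]


# CNV shares the gene-by-sample layout; values are copy-number estimates
# (0 neutral, <0 deletion, >0 amplification) rather than log2 expression.
class CNVMatrix(ExpressionMatrix):
    pass


@dataclass(frozen=True)
class GeneSet:
    """Named set of gene symbols."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise DataIOError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def intersect(self, universe: Iterable[str]) -> frozenset[str]:
        present = self.genes & set(universe)
        dropped = self.genes - present
        if dropped:
            logger.warning(
                "gene set %s: %d/%d symbols absent from matrix (e.g. %s)",
                self.name, len(dropped), len(self.genes), sorted(dropped)[:3],
            )
        return present


@dataclass(frozen=True)
class GeneSetPair:
    """The signature itself: genes up- (pos) and down-regulated (neg) with progression."""

    pos: GeneSet
    neg: GeneSet

    def __post_init__(self) -> None:
        if self.pos.genes & self.neg.genes:
            raise DataIOError("pos and neg gene sets must be disjoint")


@dataclass
class CohortClinical:
    """Per-sample survival data and stratification covariates.

    Backed by a DataFrame with the fixed columns in ``CLINICAL_COLUMNS``.
    NT samples carry no survival information (os_days/event are NaN).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
        if missing:
            raise DataIOError(f"clinical table missing columns: {missing}")
        df = df.loc[:, list(CLINICAL_COLUMNS)].reset_index(drop=True)
        _check_unique(list(df["sample_id"]), "sample")
        bad = ~df["tissue_group"].isin(TISSUE_GROUPS)
        if bad.any():
            raise DataIOError(
                f"unknown tissue_group values: {sorted(df.loc[bad, 'tissue_group'].unique())}"
            )
        for col, levels in (
            ("gender", GENDERS),
            ("grade", GRADES),
            ("idh", IDH_LEVELS),
            ("mgmt", MGMT_LEVELS),
            ("subtype", SUBTYPES),
            ("chemo", YESNO),
            ("radio", YESNO),
        ):
            vals = df[col].dropna()
            bad_vals = sorted(set(vals) - set(levels))
            if bad_vals:
                raise DataIOError(f"unknown {col} values: {bad_vals}")
        df["os_days"] = pd.to_numeric(df["os_days"], errors="raise")
        df["event"] = pd.to_numeric(df["event"], errors="raise")
        if (df["os_days"].dropna() < 0).any():
            raise DataIOError("negative os_days")
        ev = df["event"].dropna()
        if not ev.isin([0, 1]).all():
            raise DataIOError("event values must be 0 or 1")
        tumour = df["tissue_group"] != "NT"
        if df.loc[tumour, "os_days"].isna().any() or df.loc[tumour, "event"].isna().any():
            raise DataIOError("tumour samples must carry os_days and event")
        self.table = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def tumour_samples(self) -> list[str]:
        t = self.table
        return list(t.loc[t["tissue_group"] != "NT", "sample_id"])

    def survival(self, sample_ids: Sequence[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(times, events) for the given tumour samples (default: all tumours)."""
        t = self.table.set_index("sample_id")
        ids = sample_ids if sample_ids is not None else self.tumour_samples()
        sub = t.loc[list(ids)]
        if sub["os_days"].isna().any():
            raise DataIOError("requested survival for samples without os_days")
        return sub["os_days"].to_numpy(float), sub["event"].to_numpy(int)

    def subset(self, sample_ids: Sequence[str]) -> "CohortClinical":
        t = self.table.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return CohortClinical(t)


@dataclass
class MutationTable:
    """Long-format per-(sample, gene) mutation indicator."""

    table: pd.DataFrame  # columns: sample_id, gene, mutated

    def __post_init__(self) -> None:
        df = self.table
        for c in ("sample_id", "gene", "mutated"):
            if c not in df.columns:
                raise DataIOError(f"mutation table missing column {c!r}")
        df = df.loc[:, ["sample_id", "gene", "mutated"]].reset_index(drop=True)
        if df.duplicated(["sample_id", "gene"]).any():
            raise DataIOError("duplicate (sample, gene) mutation records")
        mut = pd.to_numeric(df["mutated"], errors="raise")
        if not mut.isin([0, 1]).all():
            raise DataIOError("mutated must be 0 or 1")
        df["mutated"] = mut.astype(bool)
        self.table = df

    @property
    def genes(self) -> list[str]:
        return sorted(self.table["gene"].unique())

    def gene_status(self, gene: str) -> pd.Series:
        sub = self.table[self.table["gene"] == gene]
        return sub.set_index("sample_id")["mutated"]


# ---------------------------------------------------------------------------
# TSV / GMT round-trip readers and writers
# ---------------------------------------------------------------------------

def _read_matrix_tsv(path: str | Path, cls):
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise DataIOError(f"{path}: expected gene column plus sample columns")
        sample_ids = header[1:]
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise DataIOError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            gene_ids.append(fields[0])
            row = []
            for col, cell in zip(sample_ids, fields[1:]):
                try:
                    row.append(float(cell))
                except ValueError:
                    raise DataIOError(
                        f"{path}:{lineno}: malformed numeric cell {cell!r} "
                        f"(gene {fields[0]!r}, sample {col!r})"
                    ) from None
            rows.append(row)
    return cls(gene_ids, sample_ids, np.array(rows, dtype=float))


def _write_matrix_tsv(m: ExpressionMatrix, path: str | Path, gene_col: str) -> None:
    frame = m.to_frame()
    frame.index.name = gene_col
    frame.to_csv(path, sep="\t", float_format="%.10g")


def read_expression(path: str | Path) -> ExpressionMatrix:
    return _read_matrix_tsv(path, ExpressionMatrix)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    _write_matrix_tsv(m, path, "gene_id")


def read_cnv(path: str | Path) -> CNVMatrix:
    return _read_matrix_tsv(path, CNVMatrix)


def write_cnv(m: CNVMatrix, path: str | Path) -> None:
    _write_matrix_tsv(m, path, "gene_id")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Standard GMT: name <tab> description <tab> member genes. Description ignored."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataIOError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise DataIOError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets.append(GeneSet(name, frozenset(genes)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na", *sorted(s.genes)]) + "\n")


def read_clinical(path: str | Path) -> CohortClinical:
    df = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str}, na_values=[NA_TOKEN],
        keep_default_na=False,
    )
    return CohortClinical(df)


def write_clinical(c: CohortClinical, path: str | Path) -> None:
    out = c.table.copy()
    out.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN, float_format="%.10g")


def read_mutations(path: str | Path) -> MutationTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene": str})
    return MutationTable(df)


def write_mutations(m: MutationTable, path: str | Path) -> None:
    out = m.table.copy()
    out["mutated"] = out["mutated"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def packaged_signature_path() -> Path:
    """Path of the bundled 18-gene AP signature GMT (for scoring real cohorts)."""
    return Path(__file__).parent / "data" / "ap_signature.gmt"


def load_packaged_signature() -> GeneSetPair:
    pos, neg = None, None
    for s in read_gmt(packaged_signature_path()):
        if s.name == "POS_AP":
            pos = s
        elif s.name == "NEG_AP":
            neg = s
    if pos is None or neg is None:
        raise DataIOError("packaged signature must contain POS_AP and NEG_AP")
    return GeneSetPair(pos, neg)
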