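"""Shared data model and readers/writers for the tabular formats the pipeline touches.

Everything on disk is plain text: beta matrices, sample sheets, probe
annotations and clock coefficient tables are CSV (UTF-8, ``.`` decimal);
gene sets are GMT (tab-separated: set id, description, member symbols).

Conventions
-----------
* Beta matrices are canonically samples x probes.  Files in the wild come
  in both orientations, so the reader auto-detects: if the row labels look
  like probe ids (``cg...``/``ch...``) and the column labels do not, the
  matrix is transposed on read.
* Missing beta values are stored as missing (NaN), never as 0 -- 0 is a
  legal beta value.
* Genomic coordinates are 1-based inclusive, per array-manifest convention.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "BetaMatrix",
    "SampleSheet",
    "ProbeAnnotation",
    "ClockModel",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_probe_annotation",
    "write_probe_annotation",
    "read_clock_coefficients",
    "write_clock_model",
    "read_clock_model",
    "read_gmt",
    "write_gmt",
    "TISSUES",
    "SPECIES",
    "SEXES",
    "DISEASE_STATUSES",
    "REGIONS",
]

PROBE_ID_RE = re.compile(r"^(cg|ch)")
INTERCEPT_KEY = "(Intercept)"

TISSUES = ("liver", "blood", "skin")
SPECIES = ("cheetah", "lion", "tiger")
SEXES = ("female", "male")
DISEASE_STATUSES = ("sos_positive", "sos_suspect", "liver_other", "none", "unknown")
REGIONS = (
    "promoter",
    "5UTR",
    "exon",
    "intron",
    "3UTR",
    "upstream",
    "downstream",
    "unannotated",
)

SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "individual_id",
    "tissue",
    "species",
    "sex",
    "age_years",
    "disease_status",
    "source",
]

ANNOTATION_COLUMNS = ["probe_id", "chrom", "pos", "gene", "region"]


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:5]}")


@dataclass
class BetaMatrix:
    """Samples x probes matrix of methylation beta values in [0, 1].

    ``values`` is a dense float array with NaN marking missing entries.
    """

    sample_ids: list
    probe_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.probe_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.probe_ids)} probes"
            )
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.probe_ids, "probe ids")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.probe_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BetaMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return BetaMatrix(list(sample_ids), list(self.probe_ids), self.values[idx])


@dataclass
class SampleSheet:
    """Per-sample metadata table with a controlled vocabulary.

    Columns: sample_id, individual_id, tissue, species, sex, age_years,
    disease_status, source.  ``disease_status`` carries the five-level
    clinical annotation used in the disease contrast (explicit case
    diagnosis, suspect, other organ findings, none, unknown).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        df = df[SAMPLE_SHEET_COLUMNS].reset_index(drop=True)
        df["sample_id"] = df["sample_id"].astype(str)
        _check_unique(df["sample_id"], "sample ids")
        for col, vocab in [
            ("tissue", TISSUES),
            ("species", SPECIES),
            ("sex", SEXES),
            ("disease_status", DISEASE_STATUSES),
        ]:
            bad = set(df[col].astype(str)) - set(vocab)
            if bad:
                raise ValueError(f"invalid {col} values {sorted(bad)}; allowed: {vocab}")
        df["age_years"] = df["age_years"].astype(float)
        if (df["age_years"] < 0).any():
            raise ValueError("age_years must be non-negative")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def sample_ids(self) -> list:
        return self.data["sample_id"].tolist()

    def aligned_to(self, beta: BetaMatrix) -> pd.DataFrame:
        """Rows of the sheet reordered to the beta matrix's samples."""
        df = self.data.set_index("sample_id")
        missing = [s for s in beta.sample_ids if s not in df.index]
        if missing:
            raise KeyError(f"samples absent from sheet: {missing[:5]}")
        return df.loc[beta.sample_ids].reset_index()


@dataclass
class ProbeAnnotation:
    """Probe id, chromosome, 1-based position, adjacent gene, TSS-relative region."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        df = df[ANNOTATION_COLUMNS].reset_index(drop=True)
        df["probe_id"] = df["probe_id"].astype(str)
        _check_unique(df["probe_id"], "probe ids")
        df["pos"] = df["pos"].astype(int)
        if (df["pos"] < 1).any():
            raise ValueError("pos must be >= 1 (1-based coordinates)")
        df["gene"] = df["gene"].fillna("").astype(str)
        bad = set(df["region"].astype(str)) - set(REGIONS)
        if bad:
            raise ValueError(f"invalid regions {sorted(bad)}; allowed: {REGIONS}")
        self.data = df

    def indexed(self) -> pd.DataFrame:
        return self.data.set_index("probe_id")


@dataclass
class ClockModel:
    """Sparse penalized-regression clock: probe coefficients plus transform.

    ``coefficients`` maps probe id to a nonzero weight applied to raw beta
    values; the linear score is ``intercept + sum_j w_j * beta_ij``.  For age
    clocks the score lives on the transformed-age scale (knot ``asm``, offset
    ``offset``); for sex clocks it is a logit and ``positive_label`` names the
    class mapped to positive scores.
    """

    target: str
    intercept: float
    coefficients: dict
    asm: float = 2.0
    offset: float = 1.0
    positive_label: str | None = None
    negative_label: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.target not in ("age", "sex"):
            raise ValueError(f"target must be 'age' or 'sex', got {self.target!r}")
        if not self.asm > 0 or not self.offset > 0:
            raise ValueError("asm and offset must be positive")
        self.coefficients = {
            str(k): float(v) for k, v in self.coefficients.items() if v != 0.0
        }

    @property
    def n_cpgs(self) -> int:
        return len(self.coefficients)


# ---------------------------------------------------------------------------
# Beta matrix CSV
# ---------------------------------------------------------------------------

def _probe_like_fraction(labels) -> float:
    labels = list(labels)
    if not labels:
        return 0.0
    return float(np.mean([bool(PROBE_ID_RE.match(str(x))) for x in labels]))


def read_beta_matrix(path, on_invalid: str = "error") -> BetaMatrix:
    """Read a beta matrix CSV, auto-detecting its orientation.

    The file has one id column/header row of probe ids and one of sample
    ids; orientation is detected by matching row labels against the probe-id
    pattern ``^cg|^ch`` and transposing when rows look like probes.  Empty
    cells become missing.  Cells outside [0, 1] raise (``on_invalid='error'``,
    the message names the offending row and column) or are masked to missing
    with the count logged (``on_invalid='mask'``).
    """
    if on_invalid not in ("error", "mask"):
        raise ValueError("on_invalid must be 'error' or 'mask'")
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    rows_probe = _probe_like_fraction(df.index)
    cols_probe = _probe_like_fraction(df.columns)
    if rows_probe > cols_probe:
        df = df.T
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    raw_missing = df.isna().to_numpy()
    out_of_range = np.isfinite(values) & ((values < 0) | (values > 1))
    if out_of_range.any():
        if on_invalid == "error":
            i, j = np.argwhere(out_of_range)[0]
            raise ValueError(
                f"beta value {values[i, j]} outside [0, 1] at "
                f"row {df.index[i]!r}, column {df.columns[j]!r}"
            )
        n_masked = int(out_of_range.sum())
        logger.warning("masked %d out-of-range beta values to missing", n_masked)
        values[out_of_range] = np.nan
    # non-numeric, non-empty cells are a malformed file, not maskable data
    bad_text = np.isnan(values) & ~raw_missing & ~out_of_range
    if bad_text.any():
        i, j = np.argwhere(bad_text)[0]
        raise ValueError(
            f"non-numeric cell at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    return BetaMatrix(list(df.index), list(df.columns), values)


def write_beta_matrix(beta: BetaMatrix, path) -> None:
    beta.to_frame().to_csv(path, index_label="sample_id")


# ---------------------------------------------------------------------------
# Sample sheet / annotation CSV
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, dtype={"sample_id": str, "individual_id": str}))


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.data.to_csv(path, index=False)


def read_probe_annotation(path) -> ProbeAnnotation:
    df = pd.read_csv(path, dtype={"probe_id": str, "chrom": str})
    df["gene"] = df.get("gene", "").fillna("")
    return ProbeAnnotation(df)


def write_probe_annotation(annot: ProbeAnnotation, path) -> None:
    annot.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Clock coefficient tables
# ---------------------------------------------------------------------------

def read_clock_coefficients(
    path, asm: float = 2.0, offset: float = 1.0, target: str = "age"
) -> ClockModel:
    """Read a published-style coefficient table into a :class:`ClockModel`.

    Expects columns ``(probe_id, coefficient)`` with one reserved row
    ``(Intercept)``; zero-coefficient rows are dropped.
    """
    df = pd.read_csv(path)
    if not {"probe_id", "coefficient"} <= set(df.columns):
        raise ValueError("coefficient table needs columns 'probe_id', 'coefficient'")
    df["probe_id"] = df["probe_id"].astype(str)
    coef = pd.to_numeric(df["coefficient"], errors="coerce")
    if coef.isna().any():
        bad = df.loc[coef.isna(), "probe_id"].tolist()
        raise ValueError(f"non-numeric coefficient for {bad[:5]}")
    is_intercept = df["probe_id"] == INTERCEPT_KEY
    if is_intercept.sum() != 1:
        raise ValueError(f"expected exactly one {INTERCEPT_KEY!r} row, got {int(is_intercept.sum())}")
    intercept = float(coef[is_intercept].iloc[0])
    coefficients = dict(zip(df.loc[~is_intercept, "probe_id"], coef[~is_intercept]))
    return ClockModel(target=target, intercept=intercept, coefficients=coefficients,
                      asm=asm, offset=offset)


def write_clock_model(model: ClockModel, coef_path, sidecar_path=None) -> None:
    """Write the coefficient CSV plus an optional YAML sidecar of parameters."""
    rows = [{"probe_id": INTERCEPT_KEY, "coefficient": model.intercept}]
    rows += [
        {"probe_id": p, "coefficient": w}
        for p, w in sorted(model.coefficients.items())
    ]
    pd.DataFrame(rows).to_csv(coef_path, index=False)
    if sidecar_path is not None:
        meta = {
            "target": model.target,
            "asm": float(model.asm),
            "offset": float(model.offset),
            "positive_label": model.positive_label,
            "negative_label": model.negative_label,
        }
        with open(sidecar_path, "w") as fh:
            yaml.safe_dump(meta, fh)


def read_clock_model(coef_path, sidecar_path) -> ClockModel:
    with open(sidecar_path) as fh:
        meta = yaml.safe_load(fh)
    model = read_clock_coefficients(
        coef_path, asm=meta["asm"], offset=meta["offset"], target=meta["target"]
    )
    model.positive_label = meta.get("positive_label")
    model.negative_label = meta.get("negative_label")
    return model


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict:
    """Read GMT gene sets as ``{set_id: (description, [genes])}``."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line (need >= 3 fields): {line[:80]!r}")
            set_id, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if set_id in sets:
                raise ValueError(f"duplicate gene-set id {set_id!r}")
            sets[set_id] = (desc, genes)
    return sets


def write_gmt(gene_sets: dict, path) -> None:
    with open(path, "w") as fh:
        for set_id, (desc, genes) in gene_sets.items():
            fh.write("\t".join([set_id, desc, *genes]) + "\n")
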