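"""Typed readers and writers for the tabular and interval formats of the pipeline.

Conventions, fixed once and applied everywhere:

* Probe-manifest coordinates are 1-based (array-manifest convention).
* All BED input/output is 0-based half-open; conversion happens only at the
  BED boundary, never inside the callers.
* Chromosomes sort in natural order ``chr1..chr22, chrX, chrY``, then
  lexicographically for anything else, so "consecutive probes" is well
  defined and deterministic.
* Missing β-values are encoded as ``NA`` on disk and ``NaN`` in memory.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONSEQUENCE_CLASSES = frozenset(
    {"frameshift", "stop_gain", "canonical_splice", "start_loss", "missense", "other"}
)
LOF_CLASSES = frozenset({"frameshift", "stop_gain", "canonical_splice", "start_loss"})

_CHROM_RE = re.compile(r"^(chr)?(\d+|X|Y)$", re.IGNORECASE)


def chrom_sort_key(chrom: str) -> tuple[int, int | str]:
    """Deterministic chromosome ordering: chr1..chr22, chrX, chrY, then others."""
    m = _CHROM_RE.match(chrom)
    if m:
        body = m.group(2).upper()
        if body == "X":
            return (0, 23)
        if body == "Y":
            return (0, 24)
        return (0, int(body))
    return (1, chrom)


@dataclass
class BetaMatrix:
    """Sample × probe matrix of methylation fractions (β-values) in [0, 1].

    ``values`` is a pandas DataFrame indexed by sample id with probe ids as
    columns; missing entries are NaN.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate sample ids in beta matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate probe ids in beta matrix")
        if self.values.size == 0:
            raise ValueError("empty beta matrix")
        arr = self.values.to_numpy(dtype=float)
        bad = np.isfinite(arr) & ((arr < 0) | (arr > 1))
        if bad.any():
            raise ValueError("beta values outside [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]


@dataclass
class ProbeManifest:
    """Genomic placement of array probes; 1-based positions, sorted (chrom, pos)."""

    table: pd.DataFrame  # columns: probe_id, chrom, pos [, island_id]

    def __post_init__(self) -> None:
        t = self.table
        if t["probe_id"].duplicated().any():
            raise ValueError("duplicate probe ids in manifest")
        if (t["pos"] < 1).any():
            raise ValueError("manifest positions must be >= 1")
        keys = list(zip(map(chrom_sort_key, t["chrom"]), t["pos"].astype(int)))
        order = sorted(range(len(t)), key=keys.__getitem__)
        self.table = t.iloc[order].reset_index(drop=True)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table["probe_id"])

    def positions(self) -> pd.DataFrame:
        return self.table.set_index("probe_id")[["chrom", "pos"]]


@dataclass
class IslandSet:
    """Named CpG-island intervals, 0-based half-open."""

    intervals: pd.DataFrame  # columns: chrom, start, end, name

    def __post_init__(self) -> None:
        t = self.intervals
        if len(t) and (t["start"] >= t["end"]).any():
            raise ValueError("island interval with start >= end")
        if t["name"].duplicated().any():
            raise ValueError("duplicate island names")
        self.intervals = t.reset_index(drop=True)


@dataclass
class ExpressionMatrix:
    """Expression probes × samples (normalized, arbitrary units) with probe→gene map."""

    values: pd.DataFrame  # rows = probes, columns = samples
    probe_to_gene: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    def gene_submatrix(self, gene: str) -> pd.DataFrame:
        probes = [p for p, g in self.probe_to_gene.items() if g == gene]
        probes = [p for p in self.values.index if p in set(probes)]
        if not probes:
            raise KeyError(f"no expression probes mapped to gene {gene!r}")
        return self.values.loc[probes]


@dataclass
class VariantRecord:
    """One germline variant with the fields the rare-variant filter needs."""

    gene: str
    identifier: str
    consequence_class: str
    revel: float | None
    control_ac: int
    control_an: int
    case_carriers: int

    def __post_init__(self) -> None:
        if self.consequence_class not in CONSEQUENCE_CLASSES:
            raise ValueError(
                f"unknown consequence class {self.consequence_class!r} "
                f"for variant {self.identifier!r}"
            )
        if self.control_an <= 0:
            raise ValueError("control allele number must be > 0")
        if not 0 <= self.control_ac <= self.control_an:
            raise ValueError("control AC must satisfy 0 <= AC <= AN")
        if self.case_carriers < 0:
            raise ValueError("case carrier count must be >= 0")
        if self.revel is not None and not 0 <= self.revel <= 1:
            raise ValueError("REVEL score must lie in [0, 1]")
        has_revel = self.revel is not None
        if has_revel != (self.consequence_class == "missense"):
            logger.warning(
                "variant %s: REVEL expected iff missense (class=%s, revel=%s)",
                self.identifier,
                self.consequence_class,
                self.revel,
            )

    @property
    def control_maf_pct(self) -> float:
        return 100.0 * self.control_ac / self.control_an


# ---------------------------------------------------------------------------
# Readers / writers


def read_beta_matrix(path, samples_in_columns: bool = True) -> tuple[BetaMatrix, int]:
    """Read a β-value TSV; returns the matrix and a count of coerced cells.

    On disk rows are probes and columns are samples unless
    ``samples_in_columns`` is False (then the file is sample-rows and is
    transposed on read). Non-numeric cells and values outside [0, 1] become
    missing, counted and logged.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], dtype=str)
    if df.size == 0:
        raise ValueError(f"empty beta matrix in {path}")
    num = df.apply(pd.to_numeric, errors="coerce")
    out_of_range = num.notna() & ((num < 0) | (num > 1))
    num = num.mask(out_of_range)
    n_coerced = int((df.notna() & num.isna()).to_numpy().sum())
    if n_coerced:
        logger.warning("%d cells in %s coerced to missing", n_coerced, path)
    if samples_in_columns:
        num = num.T
    return BetaMatrix(num), n_coerced


def write_beta_matrix(bm: BetaMatrix, path, samples_in_columns: bool = True) -> None:
    df = bm.values.T if samples_in_columns else bm.values
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")


def read_manifest(path) -> ProbeManifest:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str, "pos": int})
    return ProbeManifest(df[["probe_id", "chrom", "pos"]])


def write_manifest(m: ProbeManifest, path) -> None:
    m.table.to_csv(path, sep="\t", index=False)


def read_islands(path) -> IslandSet:
    """Read a 4-column BED (0-based half-open) of named CpG islands."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name"],
        dtype={"chrom": str, "start": int, "end": int, "name": str},
    )
    return IslandSet(df)


def write_islands(islands: IslandSet, path) -> None:
    islands.intervals.to_csv(path, sep="\t", index=False, header=False)


def island_from_one_based(chrom: str, start1: int, end1: int, name: str) -> tuple:
    """Convert a 1-based inclusive span (as printed in genome browsers) to BED."""
    return (chrom, start1 - 1, end1, name)


def island_to_one_based(chrom: str, start0: int, end0: int, name: str) -> tuple:
    """Inverse of :func:`island_from_one_based`."""
    return (chrom, start0 + 1, end0, name)


def read_expression(path, probe_to_gene: dict[str, str] | None = None) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError("duplicate labels in expression matrix")
    return ExpressionMatrix(df, probe_to_gene or {})


def write_expression(em: ExpressionMatrix, path) -> None:
    em.values.to_csv(path, sep="\t", float_format="%.10g")


_VARIANT_COLS = [
    "gene",
    "identifier",
    "consequence_class",
    "revel",
    "control_ac",
    "control_an",
    "case_carriers",
]


def read_variants(path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    records = []
    for i, row in df.iterrows():
        cls = row["consequence_class"]
        if cls not in CONSEQUENCE_CLASSES:
            raise ValueError(f"unknown consequence class {cls!r} at row {i}")
        revel = row.get("revel")
        revel = None if revel is None or pd.isna(revel) or revel == "" else float(revel)
        records.append(
            VariantRecord(
                gene=row["gene"],
                identifier=row["identifier"],
                consequence_class=cls,
                revel=revel,
                control_ac=int(row["control_ac"]),
                control_an=int(row["control_an"]),
                case_carriers=int(row["case_carriers"]),
            )
        )
    return records


def write_variants(records: list[VariantRecord], path) -> None:
    rows = [
        {
            "gene": r.gene,
            "identifier": r.identifier,
            "consequence_class": r.consequence_class,
            "revel": "" if r.revel is None else f"{r.revel:g}",
            "control_ac": r.control_ac,
            "control_an": r.control_an,
            "case_carriers": r.case_carriers,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_VARIANT_COLS).to_csv(path, sep="\t", index=False)
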