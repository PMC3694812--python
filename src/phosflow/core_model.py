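"""Domain types and I/O for SILAC kinase-dead-vs-wild-type ratio tables.

The central object is the :class:`RatioMatrix`: phosphopeptides (rows,
keyed by their modified sequence) against the eight kinase-dead mutant
conditions (columns), holding replicate-collapsed mutant/WT fold-change
ratios with an explicit missingness mask.  Quantification tables arrive
as MaxQuant-style tab-delimited long tables: one row per (modified
phosphopeptide, condition, replicate).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: The eight kinases carrying kinase-dead (inactivating) alleles, i.e. the
#: interventional conditions.  Column order of every RatioMatrix.
KINASES: tuple[str, ...] = (
    "KSP1", "KSS1", "SKS1", "STE20", "SNF1", "TPK2", "ELM1", "FUS3",
)

#: SILAC channels.  "light" (Lys0/Arg0) is reserved for the WT control;
#: mutant samples occupy "medium" and "heavy".
CHANNELS: tuple[str, ...] = ("light", "medium", "heavy")

PHOSPHO_MARKER = "(ph)"


@dataclass(frozen=True)
class PhosphoPeptide:
    """A modified phosphopeptide; identity is the modified_sequence string.

    Distinct phosphosite placements on the same backbone are distinct
    peptides.  ``site_positions`` are 1-based coordinates in the protein
    sequence.
    """

    modified_sequence: str
    protein_ids: tuple[str, ...] = ()
    site_positions: tuple[int, ...] | None = None
    site_probabilities: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if PHOSPHO_MARKER not in self.modified_sequence:
            raise ValidationError(
                f"modified sequence {self.modified_sequence!r} carries no "
                f"{PHOSPHO_MARKER} marker"
            )
        if self.site_positions is not None:
            pos = self.site_positions
            if any(p < 1 for p in pos):
                raise ValidationError("site positions are 1-based (>= 1)")
            if any(b <= a for a, b in zip(pos, pos[1:])):
                raise ValidationError("site positions must be strictly increasing")
        if self.site_probabilities is not None and any(
            not 0.0 <= q <= 1.0 for q in self.site_probabilities
        ):
            raise ValidationError("site probabilities must lie in [0, 1]")

    @property
    def key(self) -> str:
        return self.modified_sequence


@dataclass(frozen=True)
class ConditionKey:
    """One mutant measurement slot: kinase KD, replicate, triplex run, channel."""

    kinase: str
    replicate: int = 1
    triplex_run: str = ""
    channel: str = "medium"

    def __post_init__(self) -> None:
        if self.kinase not in KINASES:
            raise ValidationError(
                f"unknown kinase {self.kinase!r}; allowed: {', '.join(KINASES)}"
            )
        if self.replicate < 1:
            raise ValidationError("replicate index is 1-based")
        if self.channel not in CHANNELS:
            raise ValidationError(f"unknown SILAC channel {self.channel!r}")
        if self.channel == "light":
            raise ValidationError(
                "channel 'light' is reserved for the WT control and cannot "
                "label a mutant sample"
            )


@dataclass(frozen=True)
class RatioMeasurement:
    """A single mutant/WT fold change on the linear scale."""

    ratio: float
    significance_b: float | None = None
    variability: float | None = None
    intensity: float | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ratio) and self.ratio > 0):
            raise ValidationError("ratio must be a finite positive real")
        if self.significance_b is not None and not 0.0 <= self.significance_b <= 1.0:
            raise ValidationError("significance B must lie in [0, 1]")
        if self.variability is not None and self.variability < 0:
            raise ValidationError("variability is a nonnegative percentage")

    @property
    def log2_ratio(self) -> float:
        return math.log2(self.ratio)


# ---------------------------------------------------------------------------
# Long-table I/O

#: Canonical column name -> accepted case-insensitive aliases.  A user config
#: may extend this map (design choice: aliases live in data, not parser code).
DEFAULT_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "modified_sequence": (
        "modified_sequence", "modified sequence", "sequence", "modified peptide",
    ),
    "proteins": (
        "proteins", "protein", "protein ids", "protein_ids", "leading proteins",
    ),
    "kinase": ("kinase", "condition", "mutant", "experiment"),
    "ratio": ("ratio", "ratio h/l", "ratio m/l", "fold change", "fold_change"),
    "significance_b": (
        "significance_b", "significance b", "significance b(ratio h/l)",
        "significance b(ratio m/l)", "sig_b", "sigb",
    ),
    "variability": (
        "variability", "ratio variability [%]", "variability [%]",
        "ratio h/l variability [%]",
    ),
    "replicate": ("replicate", "rep"),
    "triplex_run": ("triplex_run", "triplex run", "run", "raw file"),
}

MANDATORY_COLUMNS = ("modified_sequence", "proteins", "kinase", "ratio")
_CANONICAL_ORDER = (
    "modified_sequence", "proteins", "kinase", "ratio",
    "significance_b", "variability", "replicate", "triplex_run",
)


def _resolve_columns(
    header: Iterable[str], aliases: Mapping[str, tuple[str, ...]]
) -> dict[str, str]:
    lookup: dict[str, str] = {}
    for canonical, names in aliases.items():
        for name in names:
            lookup[name.lower().strip()] = canonical
    resolved: dict[str, str] = {}
    for col in header:
        canonical = lookup.get(col.lower().strip())
        if canonical is not None and canonical not in resolved:
            resolved[canonical] = col
    return resolved


def read_quant_table(
    path: str | Path, format_options: Mapping | None = None
) -> pd.DataFrame:
    """Read a MaxQuant-style tab-delimited long quantification table.

    Returns a DataFrame with canonical columns (modified_sequence, proteins,
    kinase, ratio, significance_b, variability, replicate, triplex_run).
    Rows whose ratio is non-numeric or non-positive are dropped; the count
    is logged and exposed as ``df.attrs["n_dropped"]``.

    Raises
    ------
    FormatError
        if a mandatory column is absent (the error names the column).
    ValidationError
        if a kinase label is not one of the eight known conditions.
    """
    opts = dict(format_options or {})
    aliases = dict(DEFAULT_COLUMN_ALIASES)
    for canonical, extra in opts.get("aliases", {}).items():
        aliases[canonical] = tuple(extra) + aliases.get(canonical, ())

    raw = pd.read_csv(path, sep="\t", dtype=str)
    resolved = _resolve_columns(raw.columns, aliases)
    for col in MANDATORY_COLUMNS:
        if col not in resolved:
            raise FormatError(f"mandatory column '{col}' not found in {path}")

    df = pd.DataFrame(
        {canon: raw[orig] for canon, orig in resolved.items()}
    )
    for col in _CANONICAL_ORDER:
        if col not in df.columns:
            df[col] = np.nan
    df = df[list(_CANONICAL_ORDER)]

    df["kinase"] = df["kinase"].str.strip().str.upper()
    unknown = sorted(set(df["kinase"]) - set(KINASES))
    if unknown:
        raise ValidationError(
            f"unknown kinase label(s) {unknown}; allowed: {', '.join(KINASES)}"
        )

    n_before = len(df)
    df["ratio"] = pd.to_numeric(df["ratio"], errors="coerce")
    df = df[df["ratio"].notna() & (df["ratio"] > 0)].copy()
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("dropped %d row(s) with non-positive or non-numeric ratio", n_dropped)

    for col in ("significance_b", "variability"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["replicate"] = (
        pd.to_numeric(df["replicate"], errors="coerce").fillna(1).astype(int)
    )
    df["triplex_run"] = df["triplex_run"].fillna("")
    df = df.reset_index(drop=True)
    df.attrs["n_dropped"] = n_dropped
    return df


def write_quant_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write canonical long records back to TSV (round-trips read_quant_table)."""
    records[list(_CANONICAL_ORDER)].to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# Ratio matrix

@dataclass
class RatioMatrix:
    """Replicate-collapsed peptides x 8-kinase grid of mutant/WT ratios.

    ``ratio``, ``significance_b`` and ``variability`` are DataFrames indexed
    by modified sequence with the eight kinases as columns; NaN marks a
    missing cell.  A cell is missing iff no replicate observed it.
    """

    peptides: list[PhosphoPeptide]
    ratio: pd.DataFrame
    significance_b: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    variability: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if list(self.ratio.columns) != list(KINASES):
            raise ValidationError("ratio matrix columns must be the 8 kinases in order")
        keys = [p.key for p in self.peptides]
        if list(self.ratio.index) != keys:
            raise ValidationError("ratio matrix rows must match the peptide list")
        if self.significance_b is None:
            self.significance_b = pd.DataFrame(
                np.nan, index=self.ratio.index, columns=self.ratio.columns
            )
        if self.variability is None:
            self.variability = pd.DataFrame(
                np.nan, index=self.ratio.index, columns=self.ratio.columns
            )
        for layer in (self.significance_b, self.variability):
            if layer.shape != self.ratio.shape:
                raise ValidationError("all matrix layers must share one shape")

    @property
    def log2(self) -> pd.DataFrame:
        return np.log2(self.ratio)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.ratio.isna()

    @property
    def n_observed(self) -> pd.Series:
        """Observed-condition count per peptide (0-8)."""
        return self.ratio.notna().sum(axis=1)

    def peptide(self, key: str) -> PhosphoPeptide:
        for p in self.peptides:
            if p.key == key:
                return p
        raise KeyError(key)

    # -- persistence ------------------------------------------------------
    def to_dir(self, out_dir: str | Path) -> dict[str, Path]:
        """Dump one TSV per layer (ratio, log2, sigB, mask) plus peptide info."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        layers = {
            "ratio": self.ratio,
            "log2": self.log2,
            "significance_b": self.significance_b,
            "variability": self.variability,
            "mask": self.missing_mask.astype(int),
        }
        for name, frame in layers.items():
            p = out / f"{name}.tsv"
            frame.to_csv(p, sep="\t", float_format="%.17g")
            paths[name] = p
        pep = pd.DataFrame(
            {
                "modified_sequence": [p.key for p in self.peptides],
                "proteins": [";".join(p.protein_ids) for p in self.peptides],
            }
        )
        p = out / "peptides.tsv"
        pep.to_csv(p, sep="\t", index=False)
        paths["peptides"] = p
        return paths

    @classmethod
    def from_dir(cls, in_dir: str | Path) -> "RatioMatrix":
        in_dir = Path(in_dir)
        def _layer(name):
            p = in_dir / f"{name}.tsv"
            if not p.exists():
                return None
            return pd.read_csv(p, sep="\t", index_col=0).rename_axis(
                index=None, columns=None
            )

        ratio = _layer("ratio")
        sigb = _layer("significance_b")
        var = _layer("variability")
        pep = pd.read_csv(in_dir / "peptides.tsv", sep="\t")
        peptides = [
            PhosphoPeptide(
                modified_sequence=row.modified_sequence,
                protein_ids=tuple(str(row.proteins).split(";")) if pd.notna(row.proteins) else (),
            )
            for row in pep.itertuples()
        ]
        return cls(peptides=peptides, ratio=ratio, significance_b=sigb, variability=var)


def collapse_replicates(records: pd.DataFrame) -> RatioMatrix:
    """Collapse long records to one measurement per (peptide, kinase) cell.

    The representative ratio is the median of the replicate fold-changes on
    the linear scale (the log2 layer is derived afterwards; the median
    commutes with the monotone log).  Significance B collapses to the
    minimum across replicates — the conservative "at least as significant"
    summary.  Variability collapses to the median.  Cells with no replicate
    stay missing.
    """
    if records.empty:
        return RatioMatrix(
            peptides=[],
            ratio=pd.DataFrame(columns=list(KINASES), dtype=float),
        )
    seq_order = list(dict.fromkeys(records["modified_sequence"]))
    grouped = records.groupby(["modified_sequence", "kinase"], sort=False)
    agg = grouped.agg(
        ratio=("ratio", "median"),
        significance_b=("significance_b", "min"),
        variability=("variability", "median"),
    ).reset_index()

    def _pivot(col: str) -> pd.DataFrame:
        wide = agg.pivot(index="modified_sequence", columns="kinase", values=col)
        wide = wide.reindex(index=seq_order, columns=list(KINASES)).astype(float)
        return wide.rename_axis(index=None, columns=None)

    proteins = records.groupby("modified_sequence", sort=False)["proteins"].first()
    peptides = [
        PhosphoPeptide(
            modified_sequence=seq,
            protein_ids=tuple(str(proteins[seq]).split(";")),
        )
        for seq in seq_order
    ]
    return RatioMatrix(
        peptides=peptides,
        ratio=_pivot("ratio"),
        significance_b=_pivot("significance_b"),
        variability=_pivot("variability"),
    )


def map_peptides_to_proteins(
    peptides: Iterable[PhosphoPeptide],
) -> dict[str, frozenset[str]]:
    """Deterministic peptide -> protein multimap.

    Peptides shared by isoforms map to every listed protein; two distinct
    peptides of one protein are the basis of protein self-connections later.
    """
    mapping: dict[str, frozenset[str]] = {}
    for pep in peptides:
        ids = tuple(i for i in pep.protein_ids if i)
        if not ids:
            raise ValidationError(
                f"peptide {pep.key!r} has an empty protein id list"
            )
        mapping[pep.key] = frozenset(ids)
    return mapping
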