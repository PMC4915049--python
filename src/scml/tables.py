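"""Count, design and qPCR tables and their tab-separated on-disk formats.

The native count-table format is plain TSV with taxa as rows and samples as
columns.  The classic QIIME-era OTU-table dialect (first header cell
``#OTU ID``) is accepted transparently on read and selectable on write.
Spike taxon roles are never inferred from taxonomy strings: they are an
explicit ``species -> taxon_id`` mapping supplied alongside the table.

All floating-point output is serialized with 10 significant digits so that
reports are byte-stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

BACKGROUND = "background"

#: significant digits used for every float written by this module
FLOAT_FMT = "%.10g"


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


# ---------------------------------------------------------------------------
# CountTable
# ---------------------------------------------------------------------------


@dataclass
class CountTable:
    """Read counts for samples x taxa, with taxon roles.

    Parameters
    ----------
    counts
        DataFrame indexed by taxon id with one column per sample
        (the classic OTU-table orientation).  Values must be non-negative,
        and integral unless ``integral=False`` (used for deterministic
        expected-count matrices, which are real-valued).
    spike_map
        Mapping ``species -> taxon_id`` for the spike-in taxa; every other
        taxon is background.  Each species maps to exactly one taxon
        (multi-OTU spike hits are collapsed upstream).
    """

    counts: pd.DataFrame
    spike_map: Mapping[str, str] = field(default_factory=dict)
    integral: bool = True

    def __post_init__(self) -> None:
        self.counts = pd.DataFrame(self.counts)
        self.spike_map = dict(self.spike_map)
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise DataError(f"duplicate taxon ids: {dupes}")
        if self.counts.columns.duplicated().any():
            dupes = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise DataError(f"duplicate sample ids: {dupes}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise DataError("count table contains non-numeric values")
        neg = np.argwhere(values < 0)
        if neg.size:
            i, j = neg[0]
            raise DataError(
                f"negative count at taxon {self.counts.index[i]!r}, "
                f"sample {self.counts.columns[j]!r}"
            )
        if self.integral:
            frac = np.argwhere(values != np.floor(values))
            if frac.size:
                i, j = frac[0]
                raise DataError(
                    f"non-integer count at taxon {self.counts.index[i]!r}, "
                    f"sample {self.counts.columns[j]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        missing = {sp: t for sp, t in self.spike_map.items() if t not in self.counts.index}
        if missing:
            raise DataError(f"spike taxa absent from count table: {missing}")

    # -- convenience accessors ------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def spike_taxa(self) -> list[str]:
        return list(self.spike_map.values())

    @property
    def background_taxa(self) -> list[str]:
        spikes = set(self.spike_taxa)
        return [t for t in self.counts.index if t not in spikes]

    def taxon_role(self, taxon_id: str) -> str:
        for species, tid in self.spike_map.items():
            if tid == taxon_id:
                return f"spike:{species}"
        return BACKGROUND

    def spike_taxon(self, species: str) -> str:
        try:
            return self.spike_map[species]
        except KeyError:
            raise DataError(f"no taxon mapped for spike species {species!r}") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.counts.index.equals(other.counts.index)
            and self.counts.columns.equals(other.counts.columns)
            and np.array_equal(self.counts.to_numpy(), other.counts.to_numpy())
            and self.spike_map == other.spike_map
        )


# ---------------------------------------------------------------------------
# DesignTable
# ---------------------------------------------------------------------------


@dataclass
class DesignTable:
    """Per-sample dilution factors and designed spike-in 16S copy amounts.

    ``dilution_factor`` is the reciprocal of the relative microbial load
    (1 = undiluted); ``spike_copies`` has one column per spike species with
    the 16S rDNA copies added by design.
    """

    dilution_factor: pd.Series
    spike_copies: pd.DataFrame

    def __post_init__(self) -> None:
        self.dilution_factor = pd.Series(self.dilution_factor, dtype=float)
        self.spike_copies = pd.DataFrame(self.spike_copies).astype(float)
        if not self.dilution_factor.index.equals(self.spike_copies.index):
            raise DataError("dilution factors and spike copies index different samples")
        if self.dilution_factor.index.duplicated().any():
            raise DataError("duplicate sample ids in design table")
        bad = self.dilution_factor[self.dilution_factor <= 0]
        if len(bad):
            raise DataError(f"non-positive dilution factor for sample {bad.index[0]!r}")
        if (self.spike_copies.to_numpy() < 0).any():
            raise DataError("negative designed spike copies")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dilution_factor.index)

    @property
    def species(self) -> list[str]:
        return list(self.spike_copies.columns)

    def copies(self, species: str) -> pd.Series:
        if species not in self.spike_copies.columns:
            raise DataError(f"species {species!r} not in design table")
        return self.spike_copies[species]

    def require_samples(self, sample_ids) -> None:
        missing = [s for s in sample_ids if s not in self.dilution_factor.index]
        if missing:
            raise DataError(f"unmatched sample(s) in design table: {missing}")

    def __eq__(self, other: object) -> bool:
        # equality to the 10-significant-digit serialization precision
        if not isinstance(other, DesignTable):
            return NotImplemented
        return (
            self.dilution_factor.index.equals(other.dilution_factor.index)
            and np.allclose(self.dilution_factor, other.dilution_factor, rtol=1e-9)
            and self.spike_copies.columns.equals(other.spike_copies.columns)
            and np.allclose(
                self.spike_copies.to_numpy(), other.spike_copies.to_numpy(), rtol=1e-9
            )
        )


@dataclass
class QpcrTable:
    """Per-sample qPCR-derived total 16S rDNA copy numbers."""

    total_copies: pd.Series

    def __post_init__(self) -> None:
        self.total_copies = pd.Series(self.total_copies, dtype=float)
        if self.total_copies.index.duplicated().any():
            raise DataError("duplicate sample ids in qPCR table")
        bad = self.total_copies[self.total_copies <= 0]
        if len(bad):
            raise DataError(f"non-positive qPCR total for sample {bad.index[0]!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.total_copies.index)

    def require_samples(self, sample_ids) -> None:
        missing = [s for s in sample_ids if s not in self.total_copies.index]
        if missing:
            raise DataError(f"unmatched sample(s) in qPCR table: {missing}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, QpcrTable):
            return NotImplemented
        return self.total_copies.index.equals(
            other.total_copies.index
        ) and np.allclose(
            self.total_copies.to_numpy(), other.total_copies.to_numpy(), rtol=1e-9
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_count_table(path, spike_map: Mapping[str, str] | None = None) -> CountTable:
    """Read a TSV count table (plain or classic ``#OTU ID`` dialect).

    The first header cell names the taxon-id column (ignored, or ``#OTU ID``
    in the classic dialect); remaining header cells are sample ids; one row
    per taxon.  Cells must be non-negative integers.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty file")
        cells = header.split("\t")
        samples = cells[1:]
        taxa: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(samples) + 1:
                raise FormatError(
                    f"{path}:{lineno}: expected {len(samples) + 1} columns, got {len(parts)}"
                )
            taxa.append(parts[0])
            row = []
            for col, cell in zip(samples, parts[1:]):
                try:
                    value = int(cell)
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-integer count {cell!r} "
                        f"(taxon {parts[0]!r}, sample {col!r})"
                    ) from None
                if value < 0:
                    raise FormatError(
                        f"{path}:{lineno}: negative count {value} "
                        f"(taxon {parts[0]!r}, sample {col!r})"
                    )
                row.append(value)
            rows.append(row)
    counts = pd.DataFrame(rows, index=taxa, columns=samples, dtype=np.int64)
    try:
        return CountTable(counts, spike_map or {})
    except DataError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_count_table(table: CountTable, path, dialect: str = "plain") -> None:
    """Write a count table as TSV; ``dialect`` is ``plain`` or ``classic``."""
    if dialect not in ("plain", "classic"):
        raise ValueError(f"unknown dialect {dialect!r}")
    first = "#OTU ID" if dialect == "classic" else "taxon_id"
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join([first, *map(str, table.counts.columns)]) + "\n")
        for taxon, row in table.counts.iterrows():
            fh.write("\t".join([str(taxon), *(str(int(v)) for v in row)]) + "\n")


def read_design_table(path, reference: str | None = None) -> DesignTable:
    """Read a design TSV with columns ``sample_id``, ``dilution_factor``,
    one column per spike species.  Spike copies may use scientific notation.
    """
    path = Path(path)
    df = _read_tsv(path)
    for col in ("sample_id", "dilution_factor"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    species = [c for c in df.columns if c not in ("sample_id", "dilution_factor")]
    if reference is not None and reference not in species:
        raise FormatError(f"{path}: missing reference-spike column {reference!r}")
    df = df.set_index("sample_id")
    try:
        design = DesignTable(
            dilution_factor=df["dilution_factor"].astype(float),
            spike_copies=df[species].astype(float),
        )
    except (DataError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if reference is not None and (design.copies(reference) <= 0).any():
        bad = design.copies(reference)
        sample = bad.index[bad <= 0][0]
        raise FormatError(
            f"{path}: reference spike {reference!r} has non-positive copies in sample {sample!r}"
        )
    return design


def write_design_table(design: DesignTable, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(["sample_id", "dilution_factor", *design.species]) + "\n")
        for sample in design.sample_ids:
            cells = [sample, _fmt(design.dilution_factor[sample])]
            cells += [_fmt(design.spike_copies.loc[sample, sp]) for sp in design.species]
            fh.write("\t".join(cells) + "\n")


def read_qpcr_table(path) -> QpcrTable:
    path = Path(path)
    df = _read_tsv(path)
    for col in ("sample_id", "total_copies"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    try:
        return QpcrTable(df.set_index("sample_id")["total_copies"].astype(float))
    except (DataError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_qpcr_table(qpcr: QpcrTable, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample_id\ttotal_copies\n")
        for sample, total in qpcr.total_copies.items():
            fh.write(f"{sample}\t{_fmt(total)}\n")


def read_spike_map(path) -> dict[str, str]:
    """Read a ``species<TAB>taxon_id`` mapping (header ``species``, ``taxon_id``)."""
    path = Path(path)
    df = _read_tsv(path)
    for col in ("species", "taxon_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df["species"].duplicated().any():
        raise FormatError(f"{path}: duplicate species in spike map")
    return dict(zip(df["species"].astype(str), df["taxon_id"].astype(str)))


def write_spike_map(spike_map: Mapping[str, str], path) -> None:
    with Path(path).open("w") as fh:
        fh.write("species\ttaxon_id\n")
        for species, taxon in spike_map.items():
            fh.write(f"{species}\t{taxon}\n")


RATIO_COLUMNS = [
    "taxon_id",
    "sample_a",
    "sample_b",
    "method",
    "observed_log2",
    "expected_log2",
    "error",
]


def write_ratio_report(ratios, path) -> None:
    """Write a RatioSet as TSV with a deterministic row order.

    Columns: taxon_id, sample_a, sample_b, method, observed_log2,
    expected_log2, error (= observed - expected; empty when no expectation).
    Rows are sorted by (taxon, sample pair, method) so equal inputs produce
    byte-identical files.
    """
    frame = ratios.to_frame()
    if frame.empty:
        raise DataError("refusing to write an empty ratio report")
    frame = frame.sort_values(
        ["taxon_id", "sample_a", "sample_b", "method"], kind="mergesort"
    )
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(RATIO_COLUMNS) + "\n")
        for rec in frame.itertuples(index=False):
            has_exp = rec.expected_log2 is not None and not (
                isinstance(rec.expected_log2, float) and np.isnan(rec.expected_log2)
            )
            exp = _fmt(rec.expected_log2) if has_exp else ""
            err = _fmt(rec.observed_log2 - rec.expected_log2) if has_exp else ""
            fh.write(
                "\t".join(
                    [
                        str(rec.taxon_id),
                        str(rec.sample_a),
                        str(rec.sample_b),
                        str(rec.method),
                        _fmt(rec.observed_log2),
                        exp,
                        err,
                    ]
                )
                + "\n"
            )


def read_ratio_report(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in RATIO_COLUMNS[:4]})
    missing = [c for c in RATIO_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for col in ("observed_log2", "expected_log2", "error"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def _read_tsv(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str).rename(
            columns=lambda c: c.strip()
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: unreadable TSV ({exc})") from exc
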