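"""Normalization of amplicon count tables.

Four schemes are implemented:

* relative abundance — each count divided by its sample's total;
* SCML by a single reference spike — counts rescaled so the reference
  spike-in count equals its across-sample mean ``s_bar`` in every sample;
* SCML by combined spikes — non-reference spike counts are first adjusted
  for their designed concentration difference to the reference, the spikes
  are summed into one artificial entity, and that sum is calibrated to its
  mean exactly like a single spike;
* qPCR total-load scaling — counts rescaled to a constant total 16S rDNA
  copy number (the mean qPCR total, an anchor that cancels in ratios).

SCML makes between-sample ratios of the same taxon estimate ratios of
absolute abundance; ratios *between* taxa remain uncalibrated because
species-specific read yields do not cancel there.

The statsmodels-style entry point is :class:`SpikeCalibration`, whose
``fit()`` returns a :class:`CalibrationResults` carrying the size factors,
the calibrated table and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .errors import DataError
from .tables import CountTable, DesignTable, QpcrTable

Mode = Literal["single", "combined"]


@dataclass
class SizeFactorSet:
    """Per-sample scale factors ``s_i`` and the anchor level ``s_bar``.

    Invariant: ``factors[i] * calibration_count(i) == reference_level`` where
    the calibration count is the raw reference-spike count (single mode) or
    the summed adjusted spike counts (combined mode).
    """

    reference_level: float
    factors: pd.Series
    mode: str  # "single:<species>" or "combined"

    def __post_init__(self) -> None:
        self.factors = pd.Series(self.factors, dtype=float)
        if self.reference_level <= 0:
            raise DataError("reference level s_bar must be positive")
        if (self.factors <= 0).any():
            bad = self.factors.index[self.factors <= 0][0]
            raise DataError(f"non-positive size factor for sample {bad!r}")


@dataclass
class AbundanceTable:
    """Calibrated or relative abundances on the same axes as a CountTable."""

    values: pd.DataFrame  # taxa x samples, reals
    scale: Literal["relative", "scml", "qpcr"]
    spike_map: dict[str, str]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def background_taxa(self) -> list[str]:
        spikes = set(self.spike_map.values())
        return [t for t in self.values.index if t not in spikes]


def relative_abundance(table: CountTable, include_spikes: bool = True) -> AbundanceTable:
    """Divide each count by its sample's total read count.

    With ``include_spikes=False`` the spike rows are kept in the table but
    excluded from the denominator, so background proportions are those of the
    endogenous community alone.
    """
    counts = table.counts.astype(float)
    if include_spikes:
        totals = counts.sum(axis=0)
    else:
        totals = counts.loc[table.background_taxa].sum(axis=0)
    zero = totals.index[totals <= 0]
    if len(zero):
        raise DataError(f"zero total count in sample {zero[0]!r}; cannot normalize")
    return AbundanceTable(counts / totals, "relative", dict(table.spike_map))


def adjust_spike_counts(
    table: CountTable, design: DesignTable, reference: str
) -> pd.DataFrame:
    """Rescale each spike's counts for its designed concentration difference
    to the reference: ``adjusted = count * c_ref / c_species`` per sample.

    A spike added at half the reference concentration has its counts doubled.
    Background rows are returned unchanged; the reference participates with
    factor 1.  Returns a real-valued matrix on the CountTable axes.
    """
    design.require_samples(table.sample_ids)
    adjusted = table.counts.astype(float).copy()
    c_ref = design.copies(reference).loc[table.sample_ids]
    if (c_ref <= 0).any():
        bad = c_ref.index[c_ref <= 0][0]
        raise DataError(f"reference {reference!r} has zero designed copies in {bad!r}")
    for species, taxon in table.spike_map.items():
        c_sp = design.copies(species).loc[table.sample_ids]
        if (c_sp <= 0).any():
            bad = c_sp.index[c_sp <= 0][0]
            raise DataError(f"spike {species!r} has zero designed copies in {bad!r}")
        adjusted.loc[taxon] = adjusted.loc[taxon] * (c_ref / c_sp).to_numpy()
    return adjusted


def calibration_counts(
    table: CountTable,
    design: DesignTable | None,
    mode: Mode,
    reference: str,
) -> pd.Series:
    """The per-sample count the size factors are anchored to.

    Single mode: the raw reference-spike count.  Combined mode: the sum over
    all spikes of concentration-adjusted counts ("one artificial entity").
    """
    if mode == "single":
        return table.counts.loc[table.spike_taxon(reference)].astype(float)
    if mode == "combined":
        if design is None:
            raise DataError("combined mode requires a design table")
        adjusted = adjust_spike_counts(table, design, reference)
        return adjusted.loc[table.spike_taxa].sum(axis=0)
    raise DataError(f"unknown calibration mode {mode!r}")


def size_factors(
    table: CountTable,
    design: DesignTable | None = None,
    mode: Mode = "single",
    reference: str = "S.ruber",
) -> SizeFactorSet:
    """Per-sample SCML size factors ``s_i = s_bar / calibration_count_i``.

    ``s_bar`` is the arithmetic mean of the calibration counts over all
    samples.  A zero calibration count is a hard error: a sample without
    spike reads carries no load information and cannot be calibrated.
    """
    counts = calibration_counts(table, design, mode, reference)
    zero = counts.index[counts <= 0]
    if len(zero):
        raise DataError(
            f"sample {zero[0]!r} has zero spike calibration count and cannot be "
            "calibrated (drop it or re-sequence)"
        )
    s_bar = float(counts.mean())
    label = f"single:{reference}" if mode == "single" else "combined"
    return SizeFactorSet(s_bar, s_bar / counts, label)


def apply_calibration(table: CountTable, sf: SizeFactorSet) -> AbundanceTable:
    """Multiply every count of sample i by its size factor ``s_i``.

    After single-mode calibration the reference spike's value equals
    ``s_bar`` in every sample.  Values stay real; no re-rounding.
    """
    missing = [s for s in table.sample_ids if s not in sf.factors.index]
    if missing:
        raise DataError(f"size factors missing for sample(s): {missing}")
    factors = sf.factors.loc[table.sample_ids]
    values = table.counts.astype(float) * factors.to_numpy()[None, :]
    return AbundanceTable(values, "scml", dict(table.spike_map))


def qpcr_calibrate(table: CountTable, qpcr: QpcrTable) -> AbundanceTable:
    """Calibrate counts to the qPCR-derived total 16S copy number.

    Each sample's counts are put on the absolute copy scale:
    ``value(i,t) = count(i,t) / N_i * T_i`` with ``N_i`` the sample's library
    size and ``T_i`` its measured total copies, so every sample's values sum
    to its qPCR total.  Read counts are compositional — a library carries no
    information about scale — so the measured total must multiply the read
    *fractions*; between-sample ratios then become
    ``(relative ratio) * (T_a / T_b)``, estimates of absolute-abundance
    ratios.
    """
    qpcr.require_samples(table.sample_ids)
    totals = qpcr.total_copies.loc[table.sample_ids]
    libsize = table.counts.astype(float).sum(axis=0)
    zero = libsize.index[libsize <= 0]
    if len(zero):
        raise DataError(f"zero total count in sample {zero[0]!r}; cannot calibrate")
    values = table.counts.astype(float) * (totals / libsize).to_numpy()[None, :]
    return AbundanceTable(values, "qpcr", dict(table.spike_map))


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class SpikeCalibration:
    """SCML size-factor model for a spiked count table.

    Parameters
    ----------
    counts
        The CountTable (taxa x samples) with its spike map.
    design
        DesignTable with designed spike copies; required for combined mode
        or whenever spikes were added at unequal concentrations.
    mode
        ``"single"`` (reference spike only) or ``"combined"`` (all spikes,
        concentration-adjusted and summed).
    reference
        Species name of the reference spike-in.
    """

    def __init__(
        self,
        counts: CountTable,
        design: DesignTable | None = None,
        mode: Mode = "single",
        reference: str = "S.ruber",
    ):
        if mode not in ("single", "combined"):
            raise DataError(f"unknown calibration mode {mode!r}")
        counts.spike_taxon(reference)  # validate early
        self.counts = counts
        self.design = design
        self.mode: Mode = mode
        self.reference = reference

    def fit(self) -> "CalibrationResults":
        sf = size_factors(self.counts, self.design, self.mode, self.reference)
        calibrated = apply_calibration(self.counts, sf)
        return CalibrationResults(self, sf, calibrated)


class CalibrationResults:
    """Fitted size factors plus the calibrated table."""

    def __init__(
        self, model: SpikeCalibration, sf: SizeFactorSet, calibrated: AbundanceTable
    ):
        self.model = model
        self.size_factors = sf
        self.calibrated = calibrated

    @property
    def reference_level(self) -> float:
        return self.size_factors.reference_level

    @property
    def factors(self) -> pd.Series:
        return self.size_factors.factors

    def log2_calibrated(self, pseudocount: float = 0.0) -> pd.DataFrame:
        """log2-transformed calibrated values (zeros become -inf unless a
        pseudocount is supplied)."""
        with np.errstate(divide="ignore"):
            return np.log2(self.calibrated.values + pseudocount)

    def summary(self) -> str:
        sf = self.size_factors
        lines = [
            "SCML calibration results",
            "========================",
            f"mode:             {sf.mode}",
            f"samples:          {len(sf.factors)}",
            f"taxa:             {len(self.calibrated.taxon_ids)}"
            f" ({len(self.model.counts.spike_taxa)} spike)",
            f"s_bar (anchor):   {sf.reference_level:.6g}",
            "",
            "sample              size factor s_i",
            "------------------  ---------------",
        ]
        for sample, s in sf.factors.items():
            lines.append(f"{str(sample):<18}  {s:>15.6g}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<CalibrationResults mode={self.size_factors.mode!r} "
            f"n_samples={len(self.factors)} s_bar={self.reference_level:.4g}>"
        )
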