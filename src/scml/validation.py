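"""Validation of calibration schemes against a dilution/spike design.

For every taxon and every ordered pair of samples the observed log2 ratio of
normalized values is compared with the ratio the experimental design
expects: within-species designed-copy ratios for the non-reference spikes
(the intra-OTU comparison) and background-load ratios driven purely by the
dilution factor for all endogenous taxa.  Per-method error summaries (bias,
variance, expected-vs-observed correlation) quantify how well each
normalization calibrates ratios of absolute abundance.

Conventions: ordered pairs in both directions are materialized (under
antisymmetry this doubles n without changing the variance about a symmetric
mean); records where either underlying value is zero are dropped unless a
pseudocount is requested; the sample variance uses the n-1 denominator; the
Pearson correlation pools (expected, observed) pairs across taxa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import (
    AbundanceTable,
    SpikeCalibration,
    qpcr_calibrate,
    relative_abundance,
)
from .design import ExpectedRatios, expected_ratios
from .errors import DataError
from .tables import CountTable, DesignTable, QpcrTable

_FRAME_COLUMNS = [
    "taxon_id",
    "sample_a",
    "sample_b",
    "method",
    "basis",
    "observed_log2",
    "expected_log2",
]

#: display order for methods in reports and summaries
METHOD_ORDER = ["relative", "qpcr", "scml-single", "scml-combined"]


class RatioSet:
    """Observed (and optionally expected) log2 ratios per taxon and pair."""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in _FRAME_COLUMNS if c not in frame.columns]
        if missing:
            raise DataError(f"RatioSet frame missing columns {missing}")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()

    def filter(self, method: str | None = None, basis: str | None = None) -> "RatioSet":
        frame = self.frame
        if method is not None:
            frame = frame[frame["method"] == method]
        if basis is not None:
            frame = frame[frame["basis"] == basis]
        return RatioSet(frame.reset_index(drop=True))

    @property
    def methods(self) -> list[str]:
        return sorted(self.frame["method"].unique())

    @staticmethod
    def concat(parts: list["RatioSet"]) -> "RatioSet":
        frames = [p.frame for p in parts if len(p)]
        if not frames:
            return RatioSet(pd.DataFrame(columns=_FRAME_COLUMNS))
        return RatioSet(pd.concat(frames, ignore_index=True))


def _ordered_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    idx_a, idx_b = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    keep = idx_a != idx_b
    return idx_a[keep], idx_b[keep]


def pairwise_log2_ratios(
    values: AbundanceTable,
    taxa: list[str] | None = None,
    expected: ExpectedRatios | None = None,
    method: str | None = None,
    basis: str | None = None,
    pseudocount: float = 0.0,
) -> RatioSet:
    """All-pairs observed log2 ratios, optionally with design expectations.

    For each taxon and each ordered sample pair (a, b), a != b, with both
    values positive (after the optional pseudocount), the record carries
    ``observed_log2 = log2(value_a / value_b)`` and, when ``expected`` is
    given, the design-expected log2 ratio for that pair.
    """
    if taxa is None:
        taxa = values.taxon_ids
    if not taxa:
        raise DataError("empty taxon subset")
    samples = values.sample_ids
    if len(samples) < 2:
        raise DataError("pairwise ratios need at least 2 samples")
    mat = values.values.loc[taxa, samples].to_numpy(dtype=float) + pseudocount
    with np.errstate(divide="ignore"):
        log2 = np.log2(mat)
    ai, bi = _ordered_pairs(len(samples))
    with np.errstate(invalid="ignore"):  # -inf - -inf where both values are 0
        obs = log2[:, ai] - log2[:, bi]  # taxa x pairs
    ok = np.isfinite(log2[:, ai]) & np.isfinite(log2[:, bi])
    if expected is not None:
        exp_pair = np.array(
            [expected.lookup(samples[a], samples[b]) for a, b in zip(ai, bi)]
        )
        exp = np.broadcast_to(exp_pair, obs.shape)
    else:
        exp = np.full(obs.shape, np.nan)
    ti, pi = np.nonzero(ok)
    sample_arr = np.asarray(samples, dtype=object)
    frame = pd.DataFrame(
        {
            "taxon_id": np.asarray(taxa, dtype=object)[ti],
            "sample_a": sample_arr[ai[pi]],
            "sample_b": sample_arr[bi[pi]],
            "method": method or values.scale,
            "basis": basis or (expected.basis if expected is not None else "none"),
            "observed_log2": obs[ti, pi],
            "expected_log2": exp[ti, pi],
        }
    )
    return RatioSet(frame)


@dataclass
class ErrorSummary:
    """Bias, variance and expected/observed correlation for one method."""

    method: str
    basis: str
    n_pairs: int
    mean_error: float
    error_variance: float
    pearson_r: float  # NaN when expected values are constant (not applicable)

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "basis": self.basis,
            "n_pairs": self.n_pairs,
            "mean_error": self.mean_error,
            "error_variance": self.error_variance,
            "pearson_r": self.pearson_r,
        }


def summarize_errors(ratios: RatioSet) -> list[ErrorSummary]:
    """Per-(method, basis) error summaries: error = observed - expected.

    Requires every record to carry an expected value and at least two
    records per group (the sample variance is otherwise undefined).  When
    the expected values within a group are constant the correlation is not
    applicable and reported as NaN.
    """
    frame = ratios.to_frame()
    if frame.empty:
        raise DataError("cannot summarize an empty RatioSet")
    if frame["expected_log2"].isna().any():
        raise DataError("summarize_errors requires expected_log2 on every record")
    out: list[ErrorSummary] = []
    for (method, basis), grp in frame.groupby(["method", "basis"], sort=True):
        if len(grp) < 2:
            raise DataError(
                f"method {method!r} ({basis}) has {len(grp)} record(s); "
                "variance undefined"
            )
        err = grp["observed_log2"] - grp["expected_log2"]
        exp = grp["expected_log2"].to_numpy()
        obs = grp["observed_log2"].to_numpy()
        if np.ptp(exp) == 0.0 or np.ptp(obs) == 0.0:
            r = float("nan")
        else:
            r = float(stats.pearsonr(exp, obs).statistic)
        out.append(
            ErrorSummary(
                method=str(method),
                basis=str(basis),
                n_pairs=int(len(grp)),
                mean_error=float(err.mean()),
                error_variance=float(err.var(ddof=1)),
                pearson_r=r,
            )
        )
    return out


def summaries_frame(summaries: list[ErrorSummary]) -> pd.DataFrame:
    frame = pd.DataFrame([s.as_dict() for s in summaries])
    order = {m: i for i, m in enumerate(METHOD_ORDER)}
    return (
        frame.assign(_o=frame["method"].map(lambda m: order.get(m, 99)))
        .sort_values(["basis", "_o"], kind="mergesort")
        .drop(columns="_o")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class ValidationExperiment:
    """Run every normalization over a spiked dilution experiment.

    Compares relative abundance, single- and combined-spike SCML and (when a
    qPCR table is given) total-copy scaling against the design expectations:
    each non-reference spike against its designed-copy ratios, and all
    background taxa against the dilution-driven load ratios.
    """

    def __init__(
        self,
        counts: CountTable,
        design: DesignTable,
        qpcr: QpcrTable | None = None,
        reference: str = "S.ruber",
        pseudocount: float = 0.0,
    ):
        design.require_samples(counts.sample_ids)
        counts.spike_taxon(reference)  # fail early if unmapped
        self.counts = counts
        self.design = design
        self.qpcr = qpcr
        self.reference = reference
        self.pseudocount = pseudocount

    def _abundance_tables(self) -> dict[str, AbundanceTable]:
        tables = {
            "relative": relative_abundance(self.counts, include_spikes=True),
            "scml-single": SpikeCalibration(
                self.counts, self.design, "single", self.reference
            )
            .fit()
            .calibrated,
            "scml-combined": SpikeCalibration(
                self.counts, self.design, "combined", self.reference
            )
            .fit()
            .calibrated,
        }
        if self.qpcr is not None:
            tables["qpcr"] = qpcr_calibrate(self.counts, self.qpcr)
        return tables

    def fit(self) -> "ValidationResults":
        tables = self._abundance_tables()
        parts: list[RatioSet] = []
        # (a) intra-OTU: each non-reference spike against designed copies
        for species, taxon in self.counts.spike_map.items():
            if species == self.reference:
                continue
            exp = expected_ratios(self.design, "spike-concentration", species=species)
            for method, table in tables.items():
                parts.append(
                    pairwise_log2_ratios(
                        table,
                        taxa=[taxon],
                        expected=exp,
                        method=method,
                        basis="spike-concentration",
                        pseudocount=self.pseudocount,
                    )
                )
        # (b) background taxa against dilution-driven load ratios
        exp_bg = expected_ratios(self.design, "background-dilution")
        for method, table in tables.items():
            parts.append(
                pairwise_log2_ratios(
                    table,
                    taxa=self.counts.background_taxa,
                    expected=exp_bg,
                    method=method,
                    basis="background-dilution",
                    pseudocount=self.pseudocount,
                )
            )
        ratios = RatioSet.concat(parts)
        summaries = summarize_errors(ratios)
        return ValidationResults(self, ratios, summaries)


class ValidationResults:
    """RatioSet plus per-method error summaries from a validation run."""

    def __init__(
        self,
        model: ValidationExperiment,
        ratios: RatioSet,
        summaries: list[ErrorSummary],
    ):
        self.model = model
        self.ratios = ratios
        self.summaries = summaries

    @property
    def summaries_frame(self) -> pd.DataFrame:
        return summaries_frame(self.summaries)

    def error_variances(self, basis: str = "background-dilution") -> pd.Series:
        """Per-method error variance for one comparison basis."""
        frame = self.summaries_frame
        sub = frame[frame["basis"] == basis]
        return sub.set_index("method")["error_variance"]

    def correlations(self, basis: str = "background-dilution") -> pd.Series:
        frame = self.summaries_frame
        sub = frame[frame["basis"] == basis]
        return sub.set_index("method")["pearson_r"]

    def summary(self) -> str:
        lines = [
            "Validation of calibration methods against the design",
            "====================================================",
            f"samples: {len(self.model.counts.sample_ids)}   "
            f"background taxa: {len(self.model.counts.background_taxa)}   "
            f"spikes: {len(self.model.counts.spike_taxa)} "
            f"(reference {self.model.reference})",
            "",
            f"{'basis':<22} {'method':<14} {'n_pairs':>8} "
            f"{'bias':>9} {'variance':>9} {'pearson_r':>10}",
            "-" * 76,
        ]
        for row in self.summaries_frame.itertuples(index=False):
            r = "n/a" if np.isnan(row.pearson_r) else f"{row.pearson_r:.3f}"
            lines.append(
                f"{row.basis:<22} {row.method:<14} {row.n_pairs:>8d} "
                f"{row.mean_error:>9.3f} {row.error_variance:>9.3f} {r:>10}"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<ValidationResults n_records={len(self.ratios)}>"


def validate_experiment(
    counts: CountTable,
    design: DesignTable,
    qpcr: QpcrTable | None = None,
    reference: str = "S.ruber",
    pseudocount: float = 0.0,
) -> tuple[list[ErrorSummary], RatioSet]:
    """Functional wrapper around :class:`ValidationExperiment`."""
    res = ValidationExperiment(counts, design, qpcr, reference, pseudocount).fit()
    return res.summaries, res.ratios
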