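"""Synthetic spiked dilution experiments with known ground truth.

The generator emulates an OTU count table as it would come out of
closed-reference picking on a spiked dilution series: a fixed background
community whose absolute 16S copy numbers are scaled down a dilution ladder,
plus three spike-in taxa whose copy numbers are set by design.  Reads are
allocated multinomially with probabilities proportional to
``yield x copies`` — species-specific read yields model the lysis/PCR/
sequencing efficiency differences that make inter-species counts
incomparable — with optional gamma-weight overdispersion
(Dirichlet-multinomial-like) and a lognormally drawn library size.  qPCR
totals are the true total copies under independent lognormal noise.

RNG streams are split per component (abundances, depths, counts, qPCR) so
adding noise to one component does not perturb the others across seeds.
A deterministic expected-count mode supports machine-precision tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .tables import CountTable, DesignTable, QpcrTable

#: replicate-wise multipliers for the two variable spikes (2-fold ladders,
#: run in opposite directions so inter-species ratios vary across samples)
_VARIABLE_LADDER = (0.125, 0.25, 0.5, 1.0, 2.0, 4.0)

#: designed 16S copies; a few percent of the undiluted background total, so
#: spikes stay a minor constituent of the specimen while remaining countable
DEFAULT_SPIKE_BASE_COPIES = {
    "S.ruber": 3.0e8,  # reference, constant in every sample
    "R.radiobacter": 1.0e8,
    "A.acidiphilus": 5.0e7,
}

DEFAULT_YIELDS = {
    "background": 1.0,
    "S.ruber": 1.5,
    "R.radiobacter": 0.8,
    "A.acidiphilus": 0.4,
}


def default_design(
    dilution_factors=(1, 2, 4, 8, 16, 32),
    replicates_per_level: int = 6,
    reference: str = "S.ruber",
    base_copies: dict[str, float] | None = None,
) -> DesignTable:
    """A 36-sample validation design in the style of a spiked dilution series.

    The reference spike is constant; the other species follow opposing
    2-fold ladders over the replicates within each dilution level, so every
    level sees the full range of designed within-species ratios.  Table
    values are illustrative, not a reconstruction of any published design.
    """
    base = dict(base_copies or DEFAULT_SPIKE_BASE_COPIES)
    if reference not in base:
        raise DataError(f"reference {reference!r} missing from base copies")
    variable = [sp for sp in base if sp != reference]
    samples, dils, copies = [], [], {sp: [] for sp in base}
    for d in dilution_factors:
        for r in range(replicates_per_level):
            samples.append(f"D{d:g}R{r + 1}")
            dils.append(float(d))
            copies[reference].append(base[reference])
            for k, sp in enumerate(variable):
                ladder = _VARIABLE_LADDER if k % 2 == 0 else _VARIABLE_LADDER[::-1]
                copies[sp].append(base[sp] * ladder[r % len(ladder)])
    return DesignTable(
        dilution_factor=pd.Series(dils, index=samples),
        spike_copies=pd.DataFrame(copies, index=samples),
    )


@dataclass
class SimulationParams:
    """Ground-truth community, design, yields, depth and noise model.

    Defaults describe a desk-scale analog of a spiked dilution validation:
    40 background taxa with lognormal absolute 16S copies (median 1e8 per
    taxon in undiluted material), a 6-level 2-fold dilution ladder with 6
    replicates (36 samples), ~20k reads per sample, mild overdispersion and
    qPCR noise at sigma 0.7 on the natural log (a typical ~2-fold
    quantification error for universal-primer total-16S assays).
    """

    n_background_taxa: int = 40
    base_abundance_log_mean: float = float(np.log(1.0e8))
    base_abundance_log_sd: float = 1.5
    dilution_factors: tuple = (1, 2, 4, 8, 16, 32)
    replicates_per_level: int = 6
    design: DesignTable | None = None  # built by default_design when None
    reference: str = "S.ruber"
    yields: dict = field(default_factory=lambda: dict(DEFAULT_YIELDS))
    library_size_log_mean: float = float(np.log(2.0e4))
    library_size_log_sd: float = 0.25
    overdispersion: float = 0.2
    qpcr_cv: float = 0.7  # ~2-fold typical total-16S quantification error
    seed: int = 0

    def resolved_design(self) -> DesignTable:
        if self.design is not None:
            return self.design
        return default_design(
            self.dilution_factors, self.replicates_per_level, self.reference
        )

    def validate(self) -> None:
        if self.n_background_taxa < 1:
            raise DataError("need at least one background taxon")
        design = self.resolved_design()
        if len(design.sample_ids) < 1:
            raise DataError("design has no samples")
        if self.reference not in design.species:
            raise DataError(f"reference {self.reference!r} not in design")
        if "background" not in self.yields:
            raise DataError("yields must include a 'background' entry")
        for sp in design.species:
            if sp not in self.yields:
                raise DataError(f"yields missing spike species {sp!r}")
        if any(v <= 0 for v in self.yields.values()):
            raise DataError("yields must be positive")
        if self.overdispersion < 0 or self.qpcr_cv < 0:
            raise DataError("noise parameters must be non-negative")
        if self.base_abundance_log_sd < 0 or self.library_size_log_sd < 0:
            raise DataError("log-sd parameters must be non-negative")


@dataclass
class GroundTruth:
    """True per-sample loads and absolute 16S copy numbers."""

    true_load: pd.Series  # 1/dilution_factor
    true_copies: pd.DataFrame  # taxa x samples
    true_total_copies: pd.Series

    def to_frame(self) -> pd.DataFrame:
        frame = self.true_copies.T.copy()
        frame.insert(0, "true_load", self.true_load)
        frame.insert(1, "true_total_copies", self.true_total_copies)
        return frame


def spike_taxon_id(species: str) -> str:
    return f"OTU_{species}"


def _true_state(params: SimulationParams, rng_abund: np.random.Generator):
    design = params.resolved_design()
    samples = design.sample_ids
    bg_taxa = [f"BG{i + 1:03d}" for i in range(params.n_background_taxa)]
    base = rng_abund.lognormal(
        mean=params.base_abundance_log_mean,
        sigma=params.base_abundance_log_sd,
        size=params.n_background_taxa,
    )
    load = (1.0 / design.dilution_factor).rename("true_load")
    bg_copies = pd.DataFrame(
        np.outer(base, load.to_numpy()), index=bg_taxa, columns=samples
    )
    spike_taxa = [spike_taxon_id(sp) for sp in design.species]
    spike_copies = pd.DataFrame(
        design.spike_copies.T.to_numpy(), index=spike_taxa, columns=samples
    )
    copies = pd.concat([bg_copies, spike_copies])
    per_taxon_yield = np.array(
        [params.yields["background"]] * len(bg_taxa)
        + [params.yields[sp] for sp in design.species]
    )
    spike_map = {sp: spike_taxon_id(sp) for sp in design.species}
    truth = GroundTruth(load, copies, copies.sum(axis=0).rename("true_total_copies"))
    return design, copies, per_taxon_yield, spike_map, truth


def expected_counts(params: SimulationParams) -> pd.DataFrame:
    """Noise-free expected read counts: library size times the
    yield-weighted copy proportions, without any sampling."""
    params.validate()
    rng = np.random.default_rng(params.seed).spawn(1)[0]
    _, copies, yields, _, _ = _true_state(params, rng)
    weighted = copies.to_numpy() * yields[:, None]
    probs = weighted / weighted.sum(axis=0, keepdims=True)
    n = float(np.exp(params.library_size_log_mean))
    return pd.DataFrame(n * probs, index=copies.index, columns=copies.columns)


def simulate_experiment(
    params: SimulationParams, expected: bool = False
) -> tuple[CountTable, DesignTable, QpcrTable, GroundTruth]:
    """Simulate one spiked dilution experiment.

    With ``expected=True`` the stochastic sampling steps are replaced by
    their expectations (real-valued counts, noise-free qPCR totals), which
    makes calibration identities exact to machine precision.  The same seed
    always yields identical outputs.
    """
    params.validate()
    root = np.random.default_rng(params.seed)
    rng_abund, rng_depth, rng_counts, rng_qpcr = root.spawn(4)
    design, copies, yields, spike_map, truth = _true_state(params, rng_abund)
    samples = list(copies.columns)
    weighted = copies.to_numpy() * yields[:, None]
    probs = weighted / weighted.sum(axis=0, keepdims=True)

    if expected:
        n = float(np.exp(params.library_size_log_mean))
        counts = pd.DataFrame(n * probs, index=copies.index, columns=samples)
        table = CountTable(counts, spike_map, integral=False)
        qpcr = QpcrTable(truth.true_total_copies.copy())
        return table, design, qpcr, truth

    depths = rng_depth.lognormal(
        mean=params.library_size_log_mean,
        sigma=params.library_size_log_sd,
        size=len(samples),
    )
    depths = np.maximum(1, np.round(depths)).astype(np.int64)
    if params.overdispersion > 0:
        shape = 1.0 / params.overdispersion
        weights = rng_counts.gamma(shape, params.overdispersion, size=probs.shape)
        perturbed = probs * weights
        probs = perturbed / perturbed.sum(axis=0, keepdims=True)
    counts = np.empty(probs.shape, dtype=np.int64)
    for j in range(len(samples)):
        counts[:, j] = rng_counts.multinomial(depths[j], probs[:, j])
    table = CountTable(
        pd.DataFrame(counts, index=copies.index, columns=samples), spike_map
    )
    noise = (
        rng_qpcr.lognormal(mean=0.0, sigma=params.qpcr_cv, size=len(samples))
        if params.qpcr_cv > 0
        else np.ones(len(samples))
    )
    qpcr = QpcrTable(truth.true_total_copies * noise)
    return table, design, qpcr, truth
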