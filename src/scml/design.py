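"""Design-side arithmetic for spiked dilution experiments.

Converts between cell counts, OD600 readings and 16S rRNA gene copies, and
derives the loads and log2 ratios a validation experiment expects by design.
Spike amounts are always expressed in 16S rDNA copies, not cells: species
differ in rRNA operon multiplicity, so equal copy numbers generally mean
unequal cell numbers.

The built-in :data:`DEFAULT_PANEL` carries the three canonical spike species
(Salinibacter ruber, Rhizobium radiobacter, Alicyclobacillus acidiphilus)
with 1, 4 and 6 16S copies per genome and their empirical OD600-to-cell
conversion factors; S. ruber is the reference.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .errors import DataError
from .tables import DesignTable

Basis = Literal["background-dilution", "spike-concentration", "inter-species"]


@dataclass(frozen=True)
class SpikeSpec:
    """One spike-in species: rRNA multiplicity and cell-density conversion."""

    species: str
    copies_per_genome: int
    cells_per_od600_ml: float
    is_reference: bool = False

    def __post_init__(self) -> None:
        if self.copies_per_genome < 1:
            raise DataError(f"{self.species}: copies_per_genome must be >= 1")
        if self.cells_per_od600_ml <= 0:
            raise DataError(f"{self.species}: cells_per_od600_ml must be positive")


class SpikePanel:
    """An ordered set of spike species with exactly one reference."""

    def __init__(self, specs: Iterable[SpikeSpec]):
        self.specs = list(specs)
        refs = [s for s in self.specs if s.is_reference]
        if len(refs) != 1:
            raise DataError(
                f"panel must name exactly one reference species, got {len(refs)}"
            )
        names = [s.species for s in self.specs]
        if len(set(names)) != len(names):
            raise DataError("duplicate species in spike panel")
        self._by_name = {s.species: s for s in self.specs}

    @property
    def reference(self) -> SpikeSpec:
        return next(s for s in self.specs if s.is_reference)

    @property
    def species(self) -> list[str]:
        return [s.species for s in self.specs]

    def __getitem__(self, species: str) -> SpikeSpec:
        try:
            return self._by_name[species]
        except KeyError:
            raise DataError(f"species {species!r} not in panel") from None

    def __iter__(self):
        return iter(self.specs)

    def __len__(self) -> int:
        return len(self.specs)


#: The canonical three-species panel: copies/genome 1, 4, 6 and OD600 factors
#: 4.6e9, 1.4e9, 1.2e9 cells/ml for S. ruber, R. radiobacter, A. acidiphilus.
DEFAULT_PANEL = SpikePanel(
    [
        SpikeSpec("S.ruber", 1, 4.6e9, is_reference=True),
        SpikeSpec("R.radiobacter", 4, 1.4e9),
        SpikeSpec("A.acidiphilus", 6, 1.2e9),
    ]
)


def cells_to_copies(cells: float, spec: SpikeSpec) -> float:
    """16S rDNA copies contributed by ``cells`` cells of a species."""
    if cells < 0:
        raise DataError("cell count must be non-negative")
    return cells * spec.copies_per_genome


def copies_to_cells(copies: float, spec: SpikeSpec) -> float:
    """Cells needed to contribute ``copies`` 16S rDNA copies."""
    if copies < 0:
        raise DataError("copy number must be non-negative")
    return copies / spec.copies_per_genome


def od600_to_cells(od_units: float, volume_ml: float, spec: SpikeSpec) -> float:
    """Cells in ``volume_ml`` ml of suspension at ``od_units`` OD600."""
    if od_units < 0 or volume_ml < 0:
        raise DataError("OD600 and volume must be non-negative")
    return od_units * volume_ml * spec.cells_per_od600_ml


def expected_load(design: DesignTable, sample: str) -> float:
    """Relative background microbial load of a sample (1 = undiluted).

    The load is the reciprocal dilution factor; the small volume change from
    adding the spike suspension is ignored, as the design expectations are
    framed purely by dilution factor and designed copies.
    """
    if sample not in design.dilution_factor.index:
        raise KeyError(f"sample {sample!r} not in design")
    return 1.0 / float(design.dilution_factor[sample])


class ExpectedRatios:
    """Design-expected log2 ratios for ordered sample pairs.

    Internally an antisymmetric S x S matrix ``log2(x_a) - log2(x_b)`` over
    some per-sample design quantity x (background load or designed spike
    copies), so antisymmetry and a zero diagonal hold by construction.
    """

    def __init__(self, per_sample_log2: pd.Series, basis: str, label: str = ""):
        self._log2 = pd.Series(per_sample_log2, dtype=float)
        self.basis = basis
        self.label = label

    @property
    def sample_ids(self) -> list[str]:
        return list(self._log2.index)

    def lookup(self, sample_a: str, sample_b: str) -> float:
        return float(self._log2[sample_a] - self._log2[sample_b])

    def series(self) -> pd.Series:
        """Per-sample log2 of the underlying design quantity."""
        return self._log2.copy()

    def to_frame(self, include_diagonal: bool = False) -> pd.DataFrame:
        rows = []
        for a, b in itertools.product(self.sample_ids, repeat=2):
            if a == b and not include_diagonal:
                continue
            rows.append((a, b, self.lookup(a, b)))
        return pd.DataFrame(rows, columns=["sample_a", "sample_b", "expected_log2"])


def expected_ratios(
    design: DesignTable,
    basis: Basis,
    species: str | None = None,
    species_pair: tuple[str, str] | None = None,
) -> ExpectedRatios:
    """Expected log2 ratios under one of three comparison bases.

    ``background-dilution``: ratios of background loads, log2(load_a/load_b);
    identical for every background taxon and independent of spike copies.
    ``spike-concentration``: within-species ratios of one spike's designed
    copies across samples (requires ``species``).
    ``inter-species``: ratios of designed copies between two species
    (requires ``species_pair``); returned for across-sample comparisons via
    :meth:`ExpectedRatios.lookup`, including the same-sample diagonal.
    """
    if basis == "background-dilution":
        loads = 1.0 / design.dilution_factor
        return ExpectedRatios(np.log2(loads), basis)
    if basis == "spike-concentration":
        if species is None:
            raise DataError("spike-concentration basis requires a species")
        copies = design.copies(species)
        if (copies <= 0).any():
            bad = copies.index[copies <= 0][0]
            raise DataError(
                f"designed copies of {species!r} must be positive "
                f"(zero in sample {bad!r})"
            )
        return ExpectedRatios(np.log2(copies), basis, label=species)
    if basis == "inter-species":
        if species_pair is None:
            raise DataError("inter-species basis requires a species pair")
        sp_a, sp_b = species_pair
        ca, cb = design.copies(sp_a), design.copies(sp_b)
        if (ca <= 0).any() or (cb <= 0).any():
            raise DataError("designed copies must be positive for inter-species ratios")
        # log2(c_a(s_a)/c_b(s_b)) = [log2 c_a(s_a) - anchor] - [log2 c_b(s_b) - anchor];
        # representable per-sample only when the two species' copy profiles are
        # proportional, so compute it directly instead.
        return _InterSpeciesRatios(np.log2(ca), np.log2(cb), label=f"{sp_a}/{sp_b}")
    raise DataError(f"unknown basis {basis!r}")


class _InterSpeciesRatios(ExpectedRatios):
    """Expected log2 of designed-copy ratios between two species."""

    def __init__(self, log2_a: pd.Series, log2_b: pd.Series, label: str):
        super().__init__(log2_a, "inter-species", label)
        self._log2_b = pd.Series(log2_b, dtype=float)

    def lookup(self, sample_a: str, sample_b: str) -> float:
        return float(self._log2[sample_a] - self._log2_b[sample_b])

    def to_frame(self, include_diagonal: bool = True) -> pd.DataFrame:
        rows = [
            (a, b, self.lookup(a, b))
            for a, b in itertools.product(self.sample_ids, repeat=2)
            if include_diagonal or a != b
        ]
        return pd.DataFrame(rows, columns=["sample_a", "sample_b", "expected_log2"])
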