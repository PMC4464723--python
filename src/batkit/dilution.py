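"""Serial-dilution design of the basophil activation test.

Allergen extracts are serially diluted in ``fold_per_step``-fold steps from an
initial ``1/initial_dilution_factor`` dilution of the stock extract.  Responses
are indexed on the log10 dilution-factor scale *d*: a higher *d* means a more
dilute stimulus, so a subject whose basophils still react at high *d* is more
sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "DilutionSeries",
    "PEANUT_SERIES",
    "SOY_SERIES",
    "BIRCH_SERIES",
    "DEFAULT_SERIES",
    "ac50_to_concentration",
]

_CONVENTIONS = ("initial-dilution", "step-index")


@dataclass(frozen=True)
class DilutionSeries:
    """A serial dilution scheme for one allergen extract.

    Parameters
    ----------
    allergen
        Name of the allergen extract (e.g. ``"peanut"``).
    n_steps
        Number of serial dilutions tested (>= 2).
    initial_dilution_factor
        Dilution of the first step relative to the stock extract.
    fold_per_step
        Fold dilution between consecutive steps (> 1).
    stock_protein_concentration_mg_ml
        Protein concentration of the undiluted extract, used only by
        :func:`ac50_to_concentration`.
    convention
        How step index *k* (1-based) maps to the log10 dilution factor *d*:
        ``"initial-dilution"`` (default) gives
        ``d = log10(initial_dilution_factor) + (k - 1) * log10(fold_per_step)``;
        ``"step-index"`` gives ``d = k``.
    """

    allergen: str
    n_steps: int
    initial_dilution_factor: float = 30.0
    fold_per_step: float = 10.0
    stock_protein_concentration_mg_ml: float | None = None
    convention: str = "initial-dilution"

    def __post_init__(self) -> None:
        if self.n_steps < 2:
            raise ValueError(f"DilutionSeries.n_steps must be >= 2, got {self.n_steps}")
        if self.fold_per_step <= 1:
            raise ValueError(
                f"DilutionSeries.fold_per_step must be > 1, got {self.fold_per_step}"
            )
        if self.initial_dilution_factor < 1:
            raise ValueError(
                "DilutionSeries.initial_dilution_factor must be >= 1, got "
                f"{self.initial_dilution_factor}"
            )
        if self.convention not in _CONVENTIONS:
            raise ValueError(
                f"DilutionSeries.convention must be one of {_CONVENTIONS}, "
                f"got {self.convention!r}"
            )

    @property
    def steps(self) -> np.ndarray:
        """1-based step indices ``[1, ..., n_steps]``."""
        return np.arange(1, self.n_steps + 1)

    def log10_dilution(self, step) -> np.ndarray | float:
        """Map step index (1-based) to log10 dilution factor *d*.

        *d* is strictly increasing in the step index under both conventions.
        """
        k = np.asarray(step, dtype=float)
        if self.convention == "step-index":
            d = k
        else:
            d = np.log10(self.initial_dilution_factor) + (k - 1) * np.log10(
                self.fold_per_step
            )
        return float(d) if np.isscalar(step) else d

    def log10_dilutions(self) -> np.ndarray:
        """*d* for every step of the series, in increasing order."""
        return self.log10_dilution(self.steps)

    @property
    def d_min(self) -> float:
        return float(self.log10_dilution(1))

    @property
    def d_max(self) -> float:
        return float(self.log10_dilution(self.n_steps))

    def with_convention(self, convention: str) -> "DilutionSeries":
        return replace(self, convention=convention)


#: The three extract designs used in the study conditions: peanut tested in 12
#: serial 10-fold dilutions, soy and birch in 5, all from an initial 1/30
#: dilution of the stock (6, 1.9 and 0.08 mg protein/ml respectively).
PEANUT_SERIES = DilutionSeries("peanut", 12, stock_protein_concentration_mg_ml=6.0)
SOY_SERIES = DilutionSeries("soy", 5, stock_protein_concentration_mg_ml=1.9)
BIRCH_SERIES = DilutionSeries("birch", 5, stock_protein_concentration_mg_ml=0.08)
DEFAULT_SERIES = {s.allergen: s for s in (PEANUT_SERIES, SOY_SERIES, BIRCH_SERIES)}


def ac50_to_concentration(
    ac50: float,
    series: DilutionSeries,
    assay_dilution_factor: float = 31.0,
) -> dict[str, float]:
    """Convert an AC50 (log10 dilution units) to protein concentrations (ng/ml).

    The mapping from the dilution coordinate back to a mass concentration is
    ambiguous: it depends on the coordinate convention and on whether the
    concentration refers to the diluted extract or to the final concentration
    in the assay tube (the extract is further diluted when added to the blood
    sample; with 5 ul of extract in a 155 ul reaction the in-well factor is 31).
    Rather than asserting one convention, all are reported.

    Returns a dict with keys ``extract_initial_dilution``,
    ``extract_step_index``, ``in_well_initial_dilution``,
    ``in_well_step_index``; values in ng/ml.
    """
    if series.stock_protein_concentration_mg_ml is None:
        raise ValueError(
            f"DilutionSeries {series.allergen!r} has no stock protein concentration"
        )
    stock_ng_ml = series.stock_protein_concentration_mg_ml * 1e6
    # "initial-dilution" coordinates: total dilution factor is 10**d.
    c_initial = stock_ng_ml / 10.0**ac50
    # "step-index" coordinates: factor is initial * fold**(d - 1).
    c_step = stock_ng_ml / (
        series.initial_dilution_factor * series.fold_per_step ** (ac50 - 1.0)
    )
    return {
        "extract_initial_dilution": c_initial,
        "extract_step_index": c_step,
        "in_well_initial_dilution": c_initial / assay_dilution_factor,
        "in_well_step_index": c_step / assay_dilution_factor,
    }
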