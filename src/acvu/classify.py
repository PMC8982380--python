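"""Cell naming, anchor-cell inference, and the AC-like threshold classifier.

Within an animal the alpha cell with the highest GFP::HLH-2 value is named
``alpha1`` and treated as the presumptive anchor cell (AC); the other alpha
is ``alpha2``, and the beta cells inherit their names from their lineage
sisters (``beta1`` is the sister of ``alpha1``).

The AC-like classifier formalises the published convention: fit the mean
and sample SD of GFP values of ACs scored in the negative control, set the
threshold one SD below the mean, and call any cell strictly above it
"AC-like".  A separate visibility rule (``call_gfp_positive``) formalises
by-eye scoring of whether a cell expresses visible GFP at all: a cell is
positive when its value exceeds the background median by ``k`` background
dispersions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import mean, stdev

from .quantify import BackgroundStats, CellMeasurement

FLAG_ALPHA_TIE = "alpha-tie"
FLAG_INCOMPLETE = "incomplete-animal"


@dataclass(frozen=True)
class ThresholdModel:
    """Control-AC fluorescence statistics and the derived AC-like cutoff."""

    mu_ac: float
    sigma_ac: float

    def __post_init__(self):
        if self.sigma_ac < 0:
            raise ValueError("sigma_ac must be >= 0")

    @property
    def threshold(self) -> float:
        return self.mu_ac - self.sigma_ac


def fit_ac_threshold(control_ac_values) -> ThresholdModel:
    """Fit the AC-like threshold from negative-control AC values.

    Mean and sample SD (n-1 denominator; control samples are small);
    threshold = mean - SD.  Requires at least two values.
    """
    values = [float(v) for v in control_ac_values]
    if len(values) < 2:
        raise ValueError(f"need >= 2 control AC values, got {len(values)}")
    mu = mean(values)
    sd = stdev(values)
    return ThresholdModel(mu_ac=mu, sigma_ac=sd)


def classify_ac_like(values, model: ThresholdModel) -> tuple[list[bool], float]:
    """Per-value AC-like calls (strictly above threshold) plus the positive
    fraction.  When building per-role tables the presumptive AC (alpha1)
    should be excluded from ``values`` by the caller."""
    calls = [float(v) > model.threshold for v in values]
    frac = sum(calls) / len(calls) if calls else float("nan")
    return calls, frac


def exclude_top_fraction(values, fraction: float):
    """Drop the ``ceil(fraction * n)`` largest values.

    Used to correct a VU-fated population for cells that actually adopted
    the AC fate (e.g. excluding the top 10% of beta cells in a Notch-null
    background before comparing VU fluorescence).  Ties break toward the
    larger value first, then input order; the relative order of retained
    values is unchanged.  Returns ``(retained values, excluded indices)``.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"fraction must lie in [0, 1), got {fraction}")
    values = list(values)
    n = len(values)
    k = math.ceil(fraction * n)
    if k == 0:
        return values, []
    order = sorted(range(n), key=lambda i: (-float(values[i]), i))
    excluded = sorted(order[:k])
    retained = [v for i, v in enumerate(values) if i not in set(excluded)]
    return retained, excluded


def call_gfp_positive(
    measurement: CellMeasurement | float,
    background_stats: BackgroundStats,
    k: float = 5.0,
) -> bool:
    """Visible-GFP call: positive iff value > median + k * dispersion of
    per-region background sums from the same stack.  ``k`` defaults to 5
    dispersions, mimicking a confident by-eye call."""
    if background_stats is None:
        raise ValueError("background statistics are required")
    value = measurement.gfp_value if isinstance(measurement, CellMeasurement) else float(measurement)
    return value > background_stats.median + k * background_stats.dispersion


# ---------------------------------------------------------------------------
# naming
# ---------------------------------------------------------------------------


def _tie_break_key(m: CellMeasurement):
    # deterministic alpha tie-break: smaller centroid x wins alpha1
    x = m.centroid[0] if m.centroid is not None else float("inf")
    return x


def name_cells(
    measurements: list[CellMeasurement],
    sister_pairs: dict | None = None,
) -> tuple[list[CellMeasurement], list[str]]:
    """Assign alpha1/alpha2/beta1/beta2 roles within one animal.

    Requires exactly two alpha-class and two beta-class non-excluded
    measurements.  ``sister_pairs`` maps each cell's identifier
    (``truth_cell_id`` when available, else label) to its sister's; when
    omitted and truth ids are present, the lineage pairing is implied, and
    otherwise each beta is assigned to the nearest alpha by centroid
    distance (one-to-one, minimising total distance).

    alpha1 is the alpha with the larger GFP value; exact ties break toward
    the smaller centroid x and flag the animal ``alpha-tie``.  Missing or
    excluded cells set every role to ``unknown`` and flag the animal.
    """
    flags: list[str] = []
    alphas = [m for m in measurements if m.cell_class == "alpha" and not m.excluded]
    betas = [m for m in measurements if m.cell_class == "beta" and not m.excluded]
    if len(alphas) != 2 or len(betas) != 2:
        for m in measurements:
            m.role = "unknown"
        return measurements, [FLAG_INCOMPLETE]

    if alphas[0].gfp_value == alphas[1].gfp_value:
        flags.append(FLAG_ALPHA_TIE)
        alphas.sort(key=_tie_break_key)
    else:
        alphas.sort(key=lambda m: -m.gfp_value)
    a1, a2 = alphas

    pairing = _sister_lookup(a1, a2, betas, sister_pairs)
    a1.role, a2.role = "alpha1", "alpha2"
    pairing[id(a1)].role = "beta1"
    pairing[id(a2)].role = "beta2"
    return measurements, flags


def _sister_lookup(a1, a2, betas, sister_pairs):
    def ident(m):
        return m.truth_cell_id if m.truth_cell_id is not None else m.label

    if sister_pairs is None and all(m.truth_cell_id for m in (a1, a2, *betas)):
        sister_pairs = {"alpha1": "beta1", "alpha2": "beta2"}
    if sister_pairs is not None:
        by_id = {ident(b): b for b in betas}
        try:
            return {id(a1): by_id[sister_pairs[ident(a1)]], id(a2): by_id[sister_pairs[ident(a2)]]}
        except KeyError as e:
            raise ValueError(f"sister pairing incomplete: missing {e}") from e
    # positional fallback: one-to-one assignment minimising total distance
    b1, b2 = betas
    if a1.centroid is None or b1.centroid is None:
        raise ValueError("centroids required for positional sister pairing")
    d_same = math.dist(a1.centroid, b1.centroid) + math.dist(a2.centroid, b2.centroid)
    d_swap = math.dist(a1.centroid, b2.centroid) + math.dist(a2.centroid, b1.centroid)
    if d_same <= d_swap:
        return {id(a1): b1, id(a2): b2}
    return {id(a1): b2, id(a2): b1}


def infer_ac(alpha_measurements: list[CellMeasurement]) -> tuple[CellMeasurement, list[str]]:
    """The alpha cell with the higher GFP value is the inferred AC (equals
    alpha1 by construction).  Exact ties break deterministically by smaller
    centroid x and are flagged."""
    if len(alpha_measurements) != 2:
        raise ValueError("exactly 2 alpha measurements required")
    a, b = alpha_measurements
    if a.gfp_value == b.gfp_value:
        return min(alpha_measurements, key=_tie_break_key), [FLAG_ALPHA_TIE]
    return (a if a.gfp_value > b.gfp_value else b), []


def ac_like_table(measurements_by_role: dict, model: ThresholdModel) -> dict:
    """Per-role AC-like fractions, excluding the presumptive AC (alpha1)."""
    out = {}
    for role, values in measurements_by_role.items():
        if role == "alpha1":
            continue
        calls, frac = classify_ac_like(values, model)
        out[role] = {"n": len(values), "n_ac_like": int(sum(calls)), "fraction": frac}
    return out
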