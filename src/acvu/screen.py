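"""RNAi-screen logic: per-animal GFP-positive cell counts, control QC
gates, strict/lenient hit criteria, and triplicate confirmation.

Each screening round carries a negative control (lacZ RNAi; GFP::HLH-2
visible in only the AC) and a positive control (lin-12/Notch RNAi;
supernumerary GFP-positive cells).  A round is scoreable only when both
gates pass: at least half the negative-control animals show exactly one
GFP-positive cell, and strictly more than half the positive-control
animals show more than one.

An experimental clone is a **strict** hit when the mean number of
GFP-positive alpha/beta cells per animal is >= 2, and a **lenient** hit
when at least one animal shows all four cells positive and at least half
the population shows more than one.  Initial hits are confirmed in
triplicate (majority rule by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import mean

from . import classify, quantify
from .synth import NoiseParams, ScreenDataset, render_animal


@dataclass
class CloneResult:
    """Per-clone counts and hit calls."""

    clone_id: str
    counts: list[int]
    scoreable: bool = True
    round_name: str = ""
    n_excluded_animals: int = 0

    def __post_init__(self):
        for c in self.counts:
            if not 0 <= c <= 4:
                raise ValueError(f"counts must lie in [0, 4], got {c}")

    @property
    def n_animals(self) -> int:
        return len(self.counts)

    @property
    def mean_count(self) -> float:
        return mean(self.counts) if self.counts else float("nan")

    @property
    def strict_hit(self) -> bool:
        return self.scoreable and call_strict(self.counts)

    @property
    def lenient_hit(self) -> bool:
        return self.scoreable and call_lenient(self.counts)

    @property
    def hit(self) -> bool:
        return self.strict_hit or self.lenient_hit


@dataclass(frozen=True)
class QCResult:
    """Round-level control gates."""

    negative_pass: bool
    positive_pass: bool

    @property
    def round_valid(self) -> bool:
        return self.negative_pass and self.positive_pass


def count_gfp_cells(cell_calls) -> int:
    """Number of GFP-positive cells among one animal's visibility calls.

    ``cell_calls`` is the per-cell boolean sequence for the (at most 4)
    non-excluded alpha/beta cells.
    """
    calls = list(cell_calls)
    if len(calls) > 4:
        raise ValueError(
            f"{len(calls)} cells for one animal; at most the 4 alpha/beta "
            "cells can be scored"
        )
    return int(sum(bool(c) for c in calls))


def evaluate_controls(lacz_counts, lin12_counts) -> QCResult:
    """Apply the two control gates.

    Negative gate: fraction of lacZ animals with exactly one GFP-positive
    cell must be >= 1/2.  Positive gate: fraction of lin-12 animals with
    more than one GFP-positive cell must be strictly > 1/2.
    """
    lacz_counts, lin12_counts = list(lacz_counts), list(lin12_counts)
    if not lacz_counts or not lin12_counts:
        raise ValueError("both control count lists must be non-empty")
    neg = sum(c == 1 for c in lacz_counts) / len(lacz_counts) >= 0.5
    pos = sum(c > 1 for c in lin12_counts) / len(lin12_counts) > 0.5
    return QCResult(negative_pass=neg, positive_pass=pos)


def call_strict(counts) -> bool:
    """Strict criterion: mean GFP-positive cells per animal >= 2."""
    counts = list(counts)
    if not counts:
        raise ValueError("counts must be non-empty")
    return mean(counts) >= 2.0


def call_lenient(counts) -> bool:
    """Lenient criterion: some animal with all 4 cells positive, and at
    least half the population with more than one positive cell."""
    counts = list(counts)
    if not counts:
        raise ValueError("counts must be non-empty")
    return any(c == 4 for c in counts) and sum(c > 1 for c in counts) / len(counts) >= 0.5


def confirm_candidate(replicate_counts, rule: str = "majority") -> tuple[bool, list[bool]]:
    """Triplicate confirmation of an initial hit.

    Each replicate passes when it meets the strict or the lenient
    criterion.  ``rule='majority'`` (default) confirms on >= 2 of 3 passing
    replicates -- robust to one failed replicate; ``'all'`` and ``'any'``
    are available since the confirmation stringency is a judgement call.
    """
    if len(replicate_counts) != 3:
        raise ValueError(f"exactly 3 replicates required, got {len(replicate_counts)}")
    calls = [call_strict(c) or call_lenient(c) for c in replicate_counts]
    need = {"majority": 2, "all": 3, "any": 1}[rule]
    return sum(calls) >= need, calls


# ---------------------------------------------------------------------------
# running a whole synthetic screen end to end
# ---------------------------------------------------------------------------


@dataclass
class ScreenReport:
    clones: list
    qc: dict  # round name -> QCResult
    invalid_rounds: list
    hits: list  # clone ids called (strict or lenient) in valid rounds
    confusion: dict | None = None
    warnings: list = field(default_factory=list)


def score_animal(stack, truths, k: float = 5.0) -> int | None:
    """Count visible-GFP cells in one rendered animal, or None when the
    animal fails segmentation QC.

    Visibility of each cell is judged against background statistics from
    regions of that nucleus' own planar footprint, over the same z-slices
    the measurement used, tiled outside the larva.
    """
    meas, flags, segments = quantify.measure_animal(
        stack, method=quantify.METHOD_B, truths=truths
    )
    if flags or len(meas) != len(truths):
        return None
    calls = []
    for m, seg in zip(meas, segments):
        bg = quantify.estimate_background_stats(
            stack, seg.boundary_2d, z_slices=m.z_used, min_regions=4
        )
        calls.append(classify.call_gfp_positive(m, bg, k=k))
    return count_gfp_cells(calls)


def count_condition(
    animal_specs,
    background_level: float = 2.0,
    noise: NoiseParams = NoiseParams(),
    k: float = 5.0,
) -> tuple[list[int], int]:
    """Render and score every animal of one condition.

    Returns the per-animal GFP-positive counts and the number of animals
    excluded for segmentation QC failures.
    """
    counts, excluded = [], 0
    for spec in animal_specs:
        stack, record = render_animal(spec, background_level=background_level, noise=noise)
        c = score_animal(stack, list(record.nuclei), k=k)
        if c is None:
            excluded += 1
        else:
            counts.append(c)
    return counts, excluded


def run_screen(
    dataset: ScreenDataset,
    k: float = 5.0,
    background_level: float = 2.0,
    noise: NoiseParams = NoiseParams(),
    min_animals: int = 20,
) -> ScreenReport:
    """Execute the full image-based screen on a synthetic dataset.

    For every animal: render the stack, segment nuclei from mCherry,
    measure GFP (method B), and count visible-GFP cells against the
    stack's own outside-larva background statistics.  Rounds whose control
    gates fail are excluded from hit calling; clones scored in fewer than
    ``min_animals`` animals after QC exclusions are unscoreable.  When the
    dataset carries ground-truth hit labels a confusion table is attached.
    """
    clones: list[CloneResult] = []
    qc: dict[str, QCResult] = {}
    invalid, warnings_ = [], []

    for rnd in dataset.rounds:
        per_cond = []
        for params, specs in rnd.conditions:
            counts, excl = count_condition(
                specs, background_level=background_level, noise=noise, k=k
            )
            per_cond.append((params, counts, excl))

        lacz = next(v for v in per_cond if v[0].control == "negative")
        lin12 = next(v for v in per_cond if v[0].control == "positive")
        gates = evaluate_controls(lacz[1], lin12[1])
        qc[rnd.name] = gates
        if not gates.round_valid:
            invalid.append(rnd.name)

        for params, counts, excl in per_cond:
            if params.control is not None:
                continue
            scoreable = gates.round_valid and len(counts) >= min_animals
            clones.append(
                CloneResult(
                    clone_id=params.name,
                    counts=counts,
                    scoreable=scoreable,
                    round_name=rnd.name,
                    n_excluded_animals=excl,
                )
            )

    if qc and not any(q.round_valid for q in qc.values()):
        warnings_.append("all rounds failed control QC; no clones scored")

    hits = [c.clone_id for c in clones if c.hit]
    confusion = None
    if dataset.truth_hits:
        tp = sum(1 for c in clones if c.hit and dataset.truth_hits.get(c.clone_id))
        fp = sum(1 for c in clones if c.hit and not dataset.truth_hits.get(c.clone_id))
        fn = sum(1 for c in clones if not c.hit and dataset.truth_hits.get(c.clone_id))
        tn = sum(1 for c in clones if not c.hit and not dataset.truth_hits.get(c.clone_id))
        confusion = {"tp": tp, "fp": fp, "fn": fn, "tn": tn}
    return ScreenReport(
        clones=clones,
        qc=qc,
        invalid_rounds=invalid,
        hits=hits,
        confusion=confusion,
        warnings=warnings_,
    )


# ---------------------------------------------------------------------------
# gene-library arithmetic
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LibrarySummary:
    """Composition of the screened ubiquitin-related gene library."""

    ortholog_set: int
    added_e2: int
    added_rbr: int
    clones: int
    covered_genes: int

    @property
    def total_genes(self) -> int:
        return self.ortholog_set + self.added_e2 + self.added_rbr

    @property
    def coverage_percent(self) -> float:
        return 100.0 * self.covered_genes / self.total_genes


def gene_library_summary(
    ortholog_set: int = 239,
    added_e2: int = 1,
    added_rbr: int = 7,
    clones: int = 260,
    covered_genes: int = 232,
) -> LibrarySummary:
    """Arithmetic of the screened library: a conserved human-ortholog set
    plus one literature E2 enzyme and the ring-between-ring E3 family give
    the full conserved gene list; the available feeding-RNAi clones cover a
    subset of it."""
    return LibrarySummary(
        ortholog_set=ortholog_set,
        added_e2=added_e2,
        added_rbr=added_rbr,
        clones=clones,
        covered_genes=covered_genes,
    )
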