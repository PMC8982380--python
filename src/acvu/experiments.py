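"""Reference experiments: the package's own validation battery.

Each function runs one self-contained experiment on synthetic data with
known ground truth -- quantification recovery, slice-selection and exact-
test oracle agreement, hit-call truth tables, planted-hit screen recovery,
threshold-classifier behaviour, and the empirical size of the exact
Mann-Whitney test -- and returns plain numbers.  All randomness derives
from the single seed passed in.

Problem sizes (50 recovery animals, 120 control animals, 20 screens of 10
clones x 20 animals, 10,000 null simulations) are the package's standard
validation conditions; they keep every experiment deterministic-in-seed
and quick enough to run routinely.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np
from scipy.stats import spearmanr

from . import classify, quantify, screen, stats, synth


def _seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# quantification recovery
# ---------------------------------------------------------------------------


def recovery_experiment(seed: int, n_animals: int = 50) -> dict:
    """Spearman correlation between true and measured GFP totals for both
    measurement methods, over a calibration population spanning the
    VU-to-AC dynamic range, plus the relative change of the
    background-corrected method under a uniform intensity shift."""
    specs = synth.sample_condition(synth.recovery_condition(n_animals), seed)
    true_a, meas_a, true_b, meas_b = [], [], [], []
    shift_rel = []
    for spec in specs:
        stack, rec = synth.render_animal(spec)
        truth = {n.cell_id: n.true_gfp_total for n in rec.nuclei}
        for method, (ts, ms) in (
            (quantify.METHOD_A, (true_a, meas_a)),
            (quantify.METHOD_B, (true_b, meas_b)),
        ):
            meas, flags, segs = quantify.measure_animal(
                stack, method=method, truths=list(rec.nuclei)
            )
            if flags:
                continue
            for m in meas:
                if m.truth_cell_id:
                    ts.append(truth[m.truth_cell_id])
                    ms.append(m.gfp_value)
            if method == quantify.METHOD_A:
                shifted = synth.ImageStack(
                    gfp=stack.gfp + 11.0, mcherry=stack.mcherry, larva_mask=stack.larva_mask
                )
                for seg in segs:
                    bg = quantify.select_background_region(stack, seg.boundary_2d)
                    v0 = quantify.measure_sumproj_bgcorr(stack, seg, bg).gfp_value
                    v1 = quantify.measure_sumproj_bgcorr(shifted, seg, bg).gfp_value
                    if v0 != 0:
                        shift_rel.append(abs(v1 - v0) / abs(v0))
    return {
        "spearman_sumproj": float(spearmanr(true_a, meas_a).statistic),
        "spearman_top5": float(spearmanr(true_b, meas_b).statistic),
        "background_shift_max_rel_change": float(max(shift_rel)),
        "n_cells": len(true_b),
    }


# ---------------------------------------------------------------------------
# oracle agreement
# ---------------------------------------------------------------------------


def top5_oracle_check(seed: int, n_animals: int = 20) -> dict:
    """On segmented synthetic nuclei spanning <= 8 slices, verify that the
    top-5-by-mCherry slice rule attains the brute-force best 5-subset."""
    specs = synth.sample_condition(synth.recovery_condition(n_animals), seed)
    n_checked = n_agree = 0
    for spec in specs:
        stack, rec = synth.render_animal(spec)
        segs, flags = quantify.segment_nuclei(stack)
        for seg in segs:
            zs = [z for z, _ in seg.per_slice_mcherry]
            if len(zs) > 8:
                continue
            k = min(5, len(zs))
            mch = dict(seg.per_slice_mcherry)
            best = max(
                sum(mch[z] for z in comb) for comb in itertools.combinations(zs, k)
            )
            chosen = quantify.top5_slices(seg.per_slice_mcherry, k=5)
            n_checked += 1
            if math.isclose(sum(mch[z] for z in chosen), best, rel_tol=1e-12):
                n_agree += 1
    return {"n_checked": n_checked, "n_agree": n_agree}


def mwu_enumeration_check(seed: int, n_cases: int = 40) -> dict:
    """Exact Mann-Whitney p-values vs. an independent full enumeration of
    labelings, on random tie-free samples with pooled n <= 12."""
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    for _ in range(n_cases):
        m = int(rng.integers(2, 7))
        n = int(rng.integers(2, min(13 - m, 7)))
        x = rng.normal(size=m)
        y = rng.normal(rng.uniform(-1, 1), size=n)
        p = stats.mann_whitney_u(x, y, mode="exact").p_value
        # oracle: enumerate every labelling of the pooled sample
        pooled = np.concatenate([x, y])
        order = pooled.argsort().argsort() + 1  # ranks, tie-free
        u_obs = order[:m].sum() - m * (m + 1) / 2
        us = np.array(
            [
                sum(order[list(c)]) - m * (m + 1) / 2
                for c in itertools.combinations(range(m + n), m)
            ]
        )
        p_oracle = min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))
        max_diff = max(max_diff, abs(p - p_oracle))
    return {"n_cases": n_cases, "max_abs_diff": float(max_diff)}


def fisher_enumeration_check(max_margin: int = 20) -> dict:
    """Fisher two-sided p vs. exact-fraction enumeration over every 2x2
    table whose four margin sums are all <= ``max_margin``."""
    n_tables = 0
    max_diff = 0.0
    for r1 in range(max_margin + 1):
        for r2 in range(max_margin + 1):
            n = r1 + r2
            if n == 0:
                continue
            for c1 in range(min(n, max_margin) + 1):
                c2 = n - c1
                if c2 > max_margin:
                    continue
                lo, hi = max(0, c1 - r2), min(c1, r1)
                weights = [
                    math.comb(r1, a) * math.comb(r2, c1 - a) for a in range(lo, hi + 1)
                ]
                denom = math.comb(n, c1)
                for a in range(lo, hi + 1):
                    table = [[a, r1 - a], [c1 - a, r2 - (c1 - a)]]
                    p = stats.fisher_exact_2x2(table).p_value
                    w_obs = weights[a - lo]
                    p_oracle = float(
                        Fraction(sum(w for w in weights if w <= w_obs), denom)
                    )
                    n_tables += 1
                    max_diff = max(max_diff, abs(p - p_oracle))
    return {"n_tables": n_tables, "max_abs_diff": float(max_diff)}


# ---------------------------------------------------------------------------
# hit-calling truth table
# ---------------------------------------------------------------------------


def hit_truth_table_check() -> dict:
    """Exhaustive check of the strict/lenient/QC boolean contracts on every
    count list of length 4 over {0..4} (625 cases), against direct
    predicate evaluation."""
    n_total = n_agree = 0
    ref_lin12 = [2, 2, 2]  # passing positive control for the QC check
    ref_lacz = [1, 1, 1]  # passing negative control
    for counts in itertools.product(range(5), repeat=4):
        counts = list(counts)
        mean_c = sum(counts) / 4
        strict_ref = mean_c >= 2
        lenient_ref = (4 in counts) and sum(c > 1 for c in counts) / 4 >= 0.5
        neg_ref = sum(c == 1 for c in counts) / 4 >= 0.5
        pos_ref = sum(c > 1 for c in counts) / 4 > 0.5
        qc_as_neg = screen.evaluate_controls(counts, ref_lin12)
        qc_as_pos = screen.evaluate_controls(ref_lacz, counts)
        ok = (
            screen.call_strict(counts) == strict_ref
            and screen.call_lenient(counts) == lenient_ref
            and qc_as_neg.negative_pass == neg_ref
            and qc_as_pos.positive_pass == pos_ref
            and qc_as_neg.round_valid == (neg_ref and True)
        )
        n_total += 1
        n_agree += ok
    return {"n_total": n_total, "n_agree": n_agree}


# ---------------------------------------------------------------------------
# planted-hit screen recovery
# ---------------------------------------------------------------------------


def screen_recovery_experiment(
    seed: int,
    n_screens: int = 20,
    n_clones: int = 10,
    n_hits: int = 2,
    penetrance: float = 0.9,
    n_animals: int = 20,
) -> dict:
    """Sensitivity and false-positive count of the full image-based screen
    over independently seeded replicate screens with planted hits."""
    rng = np.random.default_rng(seed)
    tp = fn = fp = 0
    for s in _seeds(seed, n_screens):
        hit_ids = rng.choice(n_clones, size=n_hits, replace=False)
        hits = tuple(f"clone-{i:02d}" for i in sorted(hit_ids))
        design = synth.default_screen_design(
            n_clones=n_clones, hit_clones=hits,
            hit_penetrance=penetrance, n_animals=n_animals,
        )
        dataset = synth.make_screen_dataset(design, seed=s)
        report = screen.run_screen(dataset)
        tp += report.confusion["tp"]
        fn += report.confusion["fn"]
        fp += report.confusion["fp"]
    sensitivity = tp / (tp + fn) if tp + fn else float("nan")
    return {
        "n_screens": n_screens,
        "sensitivity": sensitivity,
        "false_positive_clones": fp,
        "planted": tp + fn,
    }


# ---------------------------------------------------------------------------
# AC-like threshold classifier
# ---------------------------------------------------------------------------


def threshold_experiment(seed: int, n_animals: int = 120) -> dict:
    """Fit the AC-like threshold on a synthetic negative-control population
    and classify its ACs and unstabilized VUs."""
    specs = synth.sample_condition(synth.negative_control(n_animals), seed)
    ac_vals, vu_vals, visibility = [], [], {"ac": [0, 0], "vu": [0, 0]}
    for spec in specs:
        stack, rec = synth.render_animal(spec)
        meas, flags, segs = quantify.measure_animal(stack, truths=list(rec.nuclei))
        if flags:
            continue
        classify.name_cells(meas)
        truth = {n.cell_id: n for n in rec.nuclei}
        for m, seg in zip(meas, segs):
            t = truth[m.truth_cell_id]
            bg = quantify.estimate_background_stats(
                stack, seg.boundary_2d, z_slices=m.z_used, min_regions=4
            )
            visible = classify.call_gfp_positive(m, bg)
            if t.fate == "AC":
                ac_vals.append(m.gfp_value)
                visibility["ac"][visible] += 1
            elif t.fate == "VU" and not t.stabilized:
                vu_vals.append(m.gfp_value)
                visibility["vu"][visible] += 1
    model = classify.fit_ac_threshold(ac_vals)
    ac_calls, ac_frac = classify.classify_ac_like(ac_vals, model)
    vu_calls, _ = classify.classify_ac_like(vu_vals, model)
    return {
        "n_ac": len(ac_vals),
        "n_vu": len(vu_vals),
        "ac_above_fraction": ac_frac,
        "vu_above_count": int(sum(vu_calls)),
        "ac_visible_fraction": visibility["ac"][1] / max(1, sum(visibility["ac"])),
        "vu_visible_fraction": visibility["vu"][1] / max(1, sum(visibility["vu"])),
        "threshold": model.threshold,
        "mu_ac": model.mu_ac,
    }


# ---------------------------------------------------------------------------
# empirical size of the exact Mann-Whitney test
# ---------------------------------------------------------------------------


def mwu_type1_experiment(
    seed: int, n_sim: int = 10_000, m: int = 6, n: int = 6, alpha: float = 0.05
) -> dict:
    """Rejection rate of the exact two-sided test at level ``alpha`` under
    the null (both samples standard normal, tie-free)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sim):
        x = rng.standard_normal(m)
        y = rng.standard_normal(n)
        if stats.mann_whitney_u(x, y, mode="exact").p_value <= alpha:
            rejections += 1
    return {"n_sim": n_sim, "rejection_rate": rejections / n_sim}
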