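"""End-to-end benchmark computations used for validation and reporting.

Each function runs one self-contained study on synthetic inputs and
returns the headline numbers: the consolidation-oracle error, pressure
dissipation/retention under static vs cyclic loading, the symmetry and
asymmetry of the simulated surface-growth maps, shape-pipeline recovery of
planted condyle metrics, the two-group proliferation-count ratio, and the
type-I error rate of the statistics stage under a null design.
"""

from __future__ import annotations

import dataclasses as dc
import warnings

import numpy as np

from . import shape as shp
from .growth import GrowthParams
from .poro import (
    BiphasicSolver,
    BoundaryConditions,
    FieldState,
    LoadProgram,
    PoroMaterial,
    load_at_time,
    terzaghi_pressure,
    traction_forces,
)
from .study import StudyDesign, run_full_synthetic_study, simulate_growth_pair
from .synthetic import (
    LimbSpec,
    condyle_ground_truth,
    make_column_mesh,
    make_humerus_mesh,
    make_limb_surface,
    stack_to_surface,
    voxelize_surface,
)

TWO_PI = 2 * np.pi
DORSAL_AZ = 2 * np.pi / 3
VENTRAL_AZ = 4 * np.pi / 3


def terzaghi_error(n_elements: int = 20, dt_factor: float = 0.001,
                   eval_times: tuple[float, ...] = (0.05, 0.2),
                   material: PoroMaterial = PoroMaterial()) -> float:
    """Worst relative L2 error of the FE column against the series solution.

    A 20-element column under a step load, drained at the top; dt is
    ``dt_factor`` times the characteristic consolidation time H^2/c_v.
    """
    height = 1000.0
    mesh = make_column_mesh(1, 1, n_elements, (50.0, 50.0, height))
    bc = BoundaryConditions.terzaghi_column(mesh)
    solver = BiphasicSolver(mesh, material, bc)
    cv = material.consolidation_coefficient
    tchar = height**2 / cv
    dt = dt_factor * tchar
    q = 1.0
    f = traction_forces(mesh, mesh.facet_sets["top"], q)
    state = FieldState(0.0, np.zeros((mesh.n_nodes, 3)), np.zeros(mesh.n_nodes))
    z = mesh.nodes[:, 2]
    t = 0.0
    worst = 0.0
    for frac in sorted(eval_times):
        while t < frac * tchar - 1e-9:
            state = solver.step(state, f, dt)
            t += dt
        exact = terzaghi_pressure(height - z, t, q, cv, height)
        worst = max(worst, float(np.linalg.norm(state.p - exact) / np.linalg.norm(exact)))
    return worst


def static_dissipation(spec: LimbSpec = LimbSpec(),
                       material: PoroMaterial = PoroMaterial(),
                       horizon_tchars: float = 50.0) -> float:
    """Residual volume-averaged |p| under a sustained load, % of initial.

    A constant traction patch is held on the humerus; pressure is sampled
    out to ``horizon_tchars`` consolidation times.
    """
    mesh = make_humerus_mesh(spec)
    bc = BoundaryConditions.humerus(mesh)
    solver = BiphasicSolver(mesh, material, bc)
    prog = LoadProgram(profile="constant")
    sel, _ = load_at_time(prog, mesh, 0.0)
    quads = mesh.facet_sets["distal"][sel]
    tchar = spec.shaft_radius**2 / material.consolidation_coefficient
    times = np.concatenate([np.linspace(0.01, 1.0, 10),
                            np.geomspace(1.5, horizon_tchars * tchar, 40)])
    hist = solver.solve_hold(quads, prog.peak_traction, times)
    vols = mesh.element_volumes()
    pavg = np.abs(hist.element_pressure()) @ vols / vols.sum()
    return float(100.0 * pavg[-1] / pavg[1])


def cyclic_retention(spec: LimbSpec = LimbSpec(),
                     material: PoroMaterial = PoroMaterial(),
                     program: LoadProgram = LoadProgram(),
                     n_cycles: int = 3) -> float:
    """Last-cycle integrated compressive pressure, % of the first cycle."""
    mesh = make_humerus_mesh(spec)
    bc = BoundaryConditions.humerus(mesh)
    hist = BiphasicSolver(mesh, material, bc).solve_cycle(program, n_cycles=n_cycles)
    vols = mesh.element_volumes()
    pos = np.maximum(hist.element_pressure(), 0.0) @ vols / vols.sum()
    t = hist.times
    T = program.cycle_duration
    per = [float(np.trapezoid(pos[(t >= c * T) & (t <= (c + 1) * T)],
                              t[(t >= c * T) & (t <= (c + 1) * T)]))
           for c in range(n_cycles)]
    return 100.0 * per[-1] / per[0]


def _sector_mean(flat, center_az: float, distal_frac: float = 0.65,
                 half_width: float = 0.5) -> float:
    vals = np.where(flat.mask, flat.values, np.nan)
    upper = flat.meridian_centers > distal_frac * flat.meridian_centers.max()
    in_s = np.abs(((flat.azimuth_centers - center_az + np.pi) % TWO_PI) - np.pi) < half_width
    return float(np.nanmean(vals[np.ix_(upper, in_s)]))


def azimuthal_variation(flat, min_row_count: int = 8) -> float:
    """Mean over meridian rows of the azimuthal std, over the map mean."""
    vals = np.where(flat.mask, flat.values, np.nan)
    stds = []
    for r in range(vals.shape[0]):
        row = vals[r][np.isfinite(vals[r])]
        if len(row) > min_row_count:
            stds.append(row.std())
    return float(np.mean(stds) / np.nanmean(vals))


def growth_map_asymmetry(spec: LimbSpec = LimbSpec(),
                         material: PoroMaterial = PoroMaterial(),
                         program: LoadProgram = LoadProgram(),
                         params: GrowthParams = GrowthParams()) -> dict:
    """Healthy vs impaired growth maps: sector means and symmetry.

    Returns the ventral/dorsal distal-sector means of the healthy map, the
    azimuthal variation (% of mean) of the impaired map, and the impaired
    proximo-distal profile for reference.
    """
    maps, _ = simulate_growth_pair(spec, material, program, params)
    healthy, impaired = maps["healthy"], maps["impaired"]
    return {
        "healthy_ventral_mean": _sector_mean(healthy, VENTRAL_AZ),
        "healthy_dorsal_mean": _sector_mean(healthy, DORSAL_AZ),
        "impaired_azimuthal_variation_pct": 100.0 * azimuthal_variation(impaired),
        "impaired_ventral_mean": _sector_mean(impaired, VENTRAL_AZ),
        "impaired_dorsal_mean": _sector_mean(impaired, DORSAL_AZ),
    }


def shape_recovery(spec: LimbSpec = LimbSpec(),
                   spacing: tuple[float, float, float] = (3.0, 2.0, 2.0),
                   threshold: float = 0.2) -> dict:
    """Voxelized end-to-end recovery of planted condyle metrics.

    The default limb is voxelized, re-segmented and run through the full
    morphometry pipeline; errors are relative to the analytic ground truth
    of the planted features.  Scale invariance (0.5x / 2x) and mirror-twin
    consistency are measured on the analytic surface.
    """
    gt = condyle_ground_truth(spec, threshold)
    surface = make_limb_surface(spec, resolution=128)
    stack = voxelize_surface(surface.mesh, spacing)
    rec = stack_to_surface(stack, sigma_um=min(spacing))
    _, metrics, _ = shp.analyze_limb(rec, threshold=threshold)
    errs = {}
    for s in ("ventral", "dorsal"):
        sub = metrics[metrics.structure == s]
        for q in ("area", "volume"):
            got = float(sub[q].iloc[0]) if len(sub) else 0.0
            errs[f"{s}_{q}_err_pct"] = 100.0 * abs(got - gt[s][q]) / gt[s][q]

    _, base, _ = shp.analyze_limb(surface.mesh)
    drift = 0.0
    for scale in (0.5, 2.0):
        m2 = surface.mesh.copy()
        m2.apply_scale(scale)
        _, met2, _ = shp.analyze_limb(m2)
        for s in ("ventral", "dorsal"):
            a = float(base[base.structure == s].area.iloc[0])
            b = float(met2[met2.structure == s].area.iloc[0])
            drift = max(drift, 100.0 * abs(b - a) / a)

    right = make_limb_surface(dc.replace(spec, handedness="right"), resolution=128)
    _, met_r, _ = shp.analyze_limb(right.mesh, handedness="right")
    mirror_diff = 0.0
    for s in ("ventral", "dorsal"):
        a = float(base[base.structure == s].area.iloc[0])
        b = float(met_r[met_r.structure == s].area.iloc[0])
        mirror_diff = max(mirror_diff, abs(b - a))
    return {
        "max_metric_err_pct": max(errs.values()),
        "scale_drift_pct": drift,
        "mirror_metric_diff": mirror_diff,
        **errs,
    }


def proliferation_count_ratio(seed: int = 0, design: StudyDesign = StudyDesign()) -> dict:
    """Detected-count group-mean ratio of the two-group nuclei study."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_full_synthetic_study(design, seed=seed, run_simulation=False)
    ratio = float(res.count_summary.ratio.dropna().iloc[0])
    means = res.limb_metrics.groupby("group")["count"].mean()
    return {
        "ratio": ratio,
        "control_mean": float(means["control"]),
        "treated_mean": float(means["treated"]),
        "count_p_value": float(res.stats.set_index("metric").loc["count", "p_value"]),
        "ventral_area_p_value": float(res.stats.set_index("metric").loc["ventral_area", "p_value"]),
    }


def null_design() -> StudyDesign:
    """The zero-effect study design (type-I behaviour of the statistics)."""
    return StudyDesign(
        n_control=10, n_treated=10,
        count_ratio=1.0,
        ventral_height_factor=1.0,
        dorsal_height_factor=1.0,
    )


def type_one_error_rate(n_reps: int = 20, seed: int = 0, alpha: float = 0.05) -> dict:
    """Fraction of metric tests flagged significant under the null design."""
    design = null_design()
    flags = 0
    total = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_reps):
            res = run_full_synthetic_study(design, seed=seed + 1000 * rep + rep,
                                           run_simulation=False)
            p = res.stats.p_value.to_numpy()
            flags += int((p < alpha).sum())
            total += len(p)
    return {"false_positive_rate_pct": 100.0 * flags / total,
            "flags": flags, "total_tests": total}
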