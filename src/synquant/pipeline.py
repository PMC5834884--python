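"""End-to-end study pipeline.

``run_pipeline`` executes, on a synthetic two-group study, the complete
quantification chain: study generation → semithin Cavalieri volume
fractions → counting-frame synapse densities (artifact-discounted,
shrinkage-corrected) → SAS morphometry → spatial statistics → group
comparison, and assembles a report whose every number is traceable to a
stage output (seeds and a configuration hash are recorded).

The default shrinkage factor is 1.0: synthetic material is generated in
its final geometry, so no shrinkage correction applies unless the
configuration sets ``p2`` (real tissue would use the measured value,
e.g. 0.933).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import counting, morphometry, spatial, stats, stereology, synthgen
from .io import config_hash

__all__ = ["SpatialSettings", "ElementFractionParams", "StudyConfig", "run_pipeline",
           "quantify_stack"]


@dataclass(frozen=True)
class SpatialSettings:
    n_r: int = 128
    n_sim: int = 100
    functions: tuple[str, ...] = ("G", "F", "K")
    envelope_stacks_per_case: int = 1  # envelopes are costly; estimates are cheap


@dataclass(frozen=True)
class ElementFractionParams:
    """Generating means/SDs (percent) of semithin element fractions."""

    neurons: tuple[float, float] = (7.17, 0.98)
    glia: tuple[float, float] = (0.50, 0.14)
    vessels: tuple[float, float] = (3.28, 0.41)


@dataclass(frozen=True)
class StudyConfig:
    study: synthgen.StudyParams = field(default_factory=synthgen.StudyParams)
    fractions_control: ElementFractionParams = field(default_factory=ElementFractionParams)
    fractions_disease: ElementFractionParams = field(
        default_factory=lambda: ElementFractionParams(
            neurons=(5.86, 0.84), glia=(0.35, 0.12), vessels=(3.71, 0.48)))
    p2: float = 1.0
    grid: stereology.GridSpec = field(default_factory=stereology.GridSpec)
    frame_margin: float = 0.2  # guard ≥ largest plausible synapse extent
    spatial: SpatialSettings = field(default_factory=SpatialSettings)
    semithin_size_px: int = 600
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p2 <= 0:
            raise ValueError("p2 must be positive")
        if not 0 <= self.frame_margin < 0.5:
            raise ValueError("frame_margin must be in [0, 0.5)")


def quantify_stack(stack: synthgen.StackSample, frame: counting.CountingFrame,
                   p2: float = 1.0) -> dict:
    """Counting-frame density estimate for one stack.

    The counting volume is the frame volume minus the artifact volume it
    contains (artifact_fraction × frame volume, artifacts being placed
    homogeneously), then shrinkage-corrected; the two multiplicative
    corrections commute.
    """
    extents = [
        counting.SynapseExtent(f"{stack.stack_id}_syn{i}", tuple(lo), tuple(hi))
        for i, (lo, hi) in enumerate(stack.extents())
    ]
    decision = counting.apply_counting_frame(extents, frame, stack.window)
    idx = {e.synapse_id: i for i, e in enumerate(extents)}
    types = [stack.types[idx[sid]] for sid in decision.included]
    n_as = sum(t == "AS" for t in types)
    n_ss = len(types) - n_as
    artifact_in_frame = stack.artifact_fraction * frame.volume_um3
    volume, art_frac = stereology.discount_artifacts(frame.volume_um3, artifact_in_frame)
    volume = stereology.correct_measurement(volume, p2, dimension=3)
    est = counting.density_estimate(n_as, n_ss, volume)
    return {"stack_id": stack.stack_id, "decision": decision, "estimate": est,
            "artifact_fraction": art_frac, "included_ids": decision.included}


def run_pipeline(config: StudyConfig) -> dict:
    """Run the full synthetic-study pipeline; returns the report dict."""
    rng = np.random.default_rng(config.seed)
    # every stage seed, including the study generator's, derives from config.seed
    from dataclasses import replace

    study_params = replace(config.study, seed=int(rng.integers(0, 2**31 - 1)))
    study = synthgen.generate_study(study_params)

    # --- stereology: semithin volume fractions + thickness -----------------
    vf_rows = []
    thickness_records, groups_of = {}, {}
    for case in study.cases:
        fr = (config.fractions_control if case.group == "control"
              else config.fractions_disease)
        target = [max(0.0, rng.normal(*fr.neurons)), max(0.0, rng.normal(*fr.glia)),
                  max(0.0, rng.normal(*fr.vessels))]
        img = synthgen.render_semithin(tuple(target), image_size=config.semithin_size_px,
                                       seed=rng)
        grid = stereology.GridSpec(config.grid.point_area,
                                   seed=int(rng.integers(0, 2**31 - 1)))
        vf = stereology.cavalieri_point_count(img, grid)
        vf_rows.append({"case": case.case_id, "group": case.group,
                        **{f"v_{k}": v for k, v in vf.as_dict().items()},
                        "n_points": vf.n_points,
                        **{f"truth_{k}": v for k, v in img.ground_truth.items()}})
        thickness_records[case.case_id] = case.thickness_mm
        groups_of[case.case_id] = case.group
    volume_fractions = pd.DataFrame(vf_rows)
    thickness = stereology.thickness_summary(thickness_records, groups_of)

    # --- counting + morphometry + spatial, stack by stack ------------------
    stack_rows, feature_rows, spatial_rows = [], [], []
    case_of = {}
    for case in study.cases:
        for k, stack in enumerate(case.stacks):
            case_of[stack.stack_id] = case.case_id
            frame = counting.CountingFrame.from_window(stack.window, config.frame_margin)
            q = quantify_stack(stack, frame, p2=config.p2)
            row = {"stack_id": stack.stack_id, **q["estimate"].as_row(),
                   "artifact_fraction": q["artifact_fraction"]}

            # SAS morphometry on frame-included synapses
            included = set(q["included_ids"])
            for i, mesh in enumerate(stack.meshes):
                sid = f"{stack.stack_id}_syn{i}"
                if sid not in included:
                    continue
                f = morphometry.sas_features(mesh)
                feature_rows.append({
                    "stack_id": stack.stack_id, "synapse_id": sid,
                    "case": case.case_id, "group": case.group,
                    "type": stack.types[i], "area_nm2": f.area_nm2,
                    "perimeter_nm": f.perimeter_nm, "curvature": f.curvature,
                })

            # spatial statistics
            if stack.pattern.n >= 2:
                nn = spatial.nn_distances(stack.pattern)
                row["nn_mean_nm"] = float(nn.mean())
                r_grid = np.linspace(0.0, stack.window.min_side / 4.0,
                                     config.spatial.n_r)
                if k < config.spatial.envelope_stacks_per_case:
                    for fn in config.spatial.functions:
                        env = spatial.csr_envelope(
                            stack.pattern, fn, n_sim=config.spatial.n_sim,
                            seed=int(rng.integers(0, 2**31 - 1)), r_grid=r_grid)
                        spatial_rows.append({
                            "stack_id": stack.stack_id, "case": case.case_id,
                            "group": case.group, "function": fn,
                            "n_sim": env.n_simulations,
                            "outside_fraction": env.outside_fraction,
                            "verdict": env.verdict,
                        })
            else:
                row["nn_mean_nm"] = np.nan
            stack_rows.append(row)

    stack_table = pd.DataFrame(stack_rows)
    features = pd.DataFrame(feature_rows)
    spatial_table = pd.DataFrame(spatial_rows)
    group_of = {c.case_id: c.group for c in study.cases}
    agg = counting.aggregate_cases(
        stack_table, case_of, group_of,
        value_cols=["density_as", "density_ss", "density_total",
                    "pct_as", "pct_ss", "nn_mean_nm", "counting_volume_um3"])

    sas_summary = morphometry.feature_distributions(
        features[["group", "type", "area_nm2", "perimeter_nm", "curvature"]])

    # --- study-level comparison -------------------------------------------
    case_table = agg["cases"].copy()
    case_table = case_table.merge(
        thickness["cases"].rename(columns={"mean_mm": "thickness_mm"})[
            ["case", "thickness_mm"]], on="case")
    case_table = case_table.merge(
        volume_fractions[["case", "v_neurons", "v_glia", "v_vessels", "v_neuropil"]],
        on="case")
    as_area_by_case = (features[features["type"] == "AS"]
                       .groupby("case")["area_nm2"].mean().rename("as_area_nm2"))
    curv_by_case = (features[features["type"] == "AS"]
                    .groupby("case")["curvature"].mean().rename("as_curvature"))
    case_table = case_table.merge(as_area_by_case, on="case", how="left")
    case_table = case_table.merge(curv_by_case, on="case", how="left")

    pooled = {}
    as_feat = features[features["type"] == "AS"]
    grp_names = list(dict.fromkeys(case_table["group"]))
    if len(grp_names) == 2:
        a = as_feat[as_feat["group"] == grp_names[0]]["area_nm2"].to_numpy()
        b = as_feat[as_feat["group"] == grp_names[1]]["area_nm2"].to_numpy()
        if len(a) and len(b):
            pooled["as_area_distribution"] = (a, b)
    comparison = stats.compare_study(
        case_table.drop(columns=["case"]), pooled_distributions=pooled)

    lognormal_fits = {}
    for grp in grp_names:
        vals = as_feat[as_feat["group"] == grp]["area_nm2"].to_numpy()
        if len(vals) >= 3:
            fit = morphometry.fit_lognormal(vals)
            lognormal_fits[grp] = {
                "mu": fit.mu, "sigma": fit.sigma, "implied_mean_nm2": fit.mean,
                "ks_statistic": fit.ks_statistic, "ks_pvalue": fit.ks_pvalue,
                "n": fit.n,
            }

    cfg_dict = asdict(config)
    report = {
        "provenance": {
            "seed": config.seed, "config_hash": config_hash(cfg_dict),
            "n_cases": len(study.cases),
            "n_stacks": int(len(stack_table)),
            "n_synapses_counted": int(stack_table["n_total"].sum()),
        },
        "volume_fractions": volume_fractions,
        "thickness": {"cases": thickness["cases"], "groups": thickness["groups"],
                      "reduction_pct": thickness.get("reduction_pct")},
        "stacks": stack_table,
        "cases": case_table,
        "groups": agg["groups"],
        "sas_summary": sas_summary["summary"],
        "sas_lognormal": lognormal_fits,
        "spatial": spatial_table,
        "comparison": comparison,
    }
    return report
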