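"""Orchestration of the full variability study on a cohort.

Reproduces the comparison design of the emulated study: manual annotations
are reconstructed with both mesh methods (strict SSM and soft-SSM), then

  * manual inter-individual ASD — each expert's points against every other
    expert's reconstructed mesh, per method (points→mesh, because a manual
    session has no intrinsic mesh);
  * manual intra-individual ASD — first-vs-repeat sessions of one expert;
  * meshing-method fidelity — own points vs own mesh, per method;
  * semi-automatic pairwise ASD / Dice / Hausdorff (mesh↔mesh);
  * leave-one-out STAPLE-like consensus comparisons;
  * manual points vs other experts' semi-automatic meshes and vs the
    consensus of semi-automatic segmentations;
  * Wilcoxon + Bonferroni on the three manual strict-vs-soft contrasts;
  * spatial point-density and ASD maps on the model mean shape.

All randomness lives in the cohort generator: re-running the study on the
same cohort is bit-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .consensus import staple_mesh_consensus
from .geometry import GeometryError, SegmentationRecord, closest_point_on_mesh
from .metrics import (
    DEFAULT_DICE_VOXEL_MM,
    asd_mesh_to_mesh,
    asd_points_to_mesh,
    dice_meshes,
    hausdorff,
)
from .shape_model import StatisticalShapeModel, fit_ssm_to_points
from .soft_ssm import SoftFitConfig, fit_soft_ssm
from .spatial import (
    SurfaceMap,
    density_asd_rank_correlation,
    register_annotation_to_reference,
    surface_asd_map,
    surface_density_map,
)
from .stats import (
    GroupComparison,
    MetricSummary,
    compare_groups,
    cross_study_effect_sizes,
    summarize,
)
from .synthetic import CohortData

log = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    soft_cfg: SoftFitConfig = field(default_factory=SoftFitConfig)
    dice_voxel_mm: float = DEFAULT_DICE_VOXEL_MM
    consensus_tol_mm: float = 1e-4
    consensus_max_iter: int = 100
    map_bandwidth_mm: float = 5.0
    compute_dice: bool = True     # voxel Dice on pairwise/consensus tables


@dataclass
class StudyResults:
    tables: dict[str, pd.DataFrame]
    summaries: dict[str, MetricSummary]
    tests: dict[str, GroupComparison]
    effect_sizes: pd.DataFrame
    maps: dict[str, SurfaceMap]
    density_asd_rho: float
    audit: dict

    def table(self, name: str) -> pd.DataFrame:
        return self.tables[name]


def _key(rec: SegmentationRecord) -> tuple:
    a = rec.annotation
    return (a.patient_id, a.expert_id, a.method, a.session)


def run_variability_study(cohort: CohortData | str | Path,
                          cfg: StudyConfig | None = None,
                          progress: bool = False) -> StudyResults:
    if isinstance(cohort, (str, Path)):
        from .synthetic import load_cohort
        cohort = load_cohort(cohort)
    cfg = cfg or StudyConfig()
    ssm = cohort.ssm
    manual = [r for r in cohort.records if r.annotation.method == "manual"]
    semi = {_key(r): r for r in cohort.records
            if r.annotation.method == "semi_auto"}

    # ---- stage 1: manual reconstructions (both methods) -------------------
    recon: dict[tuple, dict] = {}
    for i, rec in enumerate(manual):
        if progress:
            log.info("reconstructing manual session %d/%d", i + 1,
                     len(manual))
        ann = rec.annotation
        strict = fit_ssm_to_points(ssm, ann)
        soft = fit_soft_ssm(ssm, ann, cfg.soft_cfg)
        recon[_key(rec)] = {"annotation": ann, "manual_SSM": strict.mesh,
                            "manual_soft_SSM": soft}

    patients = sorted({k[0] for k in recon} | {k[0] for k in semi})
    methods = ("manual_SSM", "manual_soft_SSM")

    # ---- stage 2: manual inter-individual (points -> other's mesh) --------
    rows = []
    for p in patients:
        keys = [k for k in recon if k[0] == p and k[3] == 0]
        for ka in keys:
            for kb in keys:
                if ka[1] == kb[1]:
                    continue
                pts = recon[ka]["annotation"].all_points()
                for m in methods:
                    rows.append((p, ka[1], kb[1], m,
                                 asd_points_to_mesh(pts, recon[kb][m])))
    manual_inter = pd.DataFrame(
        rows, columns=["patient", "expert_points", "expert_mesh", "method",
                       "asd"])

    # ---- stage 3: manual intra (session 0 <-> session 1) ------------------
    rows = []
    for (p, e, _, s), entry in recon.items():
        if s != 1:
            continue
        first = recon.get((p, e, "manual", 0))
        if first is None:
            continue
        for m in methods:
            rows.append((p, e, m, asd_points_to_mesh(
                entry["annotation"].all_points(), first[m])))
            rows.append((p, e, m, asd_points_to_mesh(
                first["annotation"].all_points(), entry[m])))
    manual_intra = pd.DataFrame(rows, columns=["patient", "expert", "method",
                                               "asd"])

    # ---- stage 4: meshing-method fidelity (own points vs own mesh) --------
    rows = []
    for (p, e, _, s), entry in recon.items():
        pts = entry["annotation"].all_points()
        for m in methods:
            rows.append((p, e, s, m, asd_points_to_mesh(pts, entry[m])))
    method_impact = pd.DataFrame(rows, columns=["patient", "expert",
                                                "session", "method", "asd"])

    # ---- stage 5: semi-auto pairwise + intra ------------------------------
    rows = []
    for p in patients:
        keys = sorted(k for k in semi if k[0] == p and k[3] == 0)
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                a, b = semi[keys[i]].mesh, semi[keys[j]].mesh
                rows.append({
                    "patient": p, "expert_a": keys[i][1],
                    "expert_b": keys[j][1],
                    "asd": asd_mesh_to_mesh(a, b),
                    "hausdorff": hausdorff(a, b),
                    "dice": dice_meshes(a, b, cfg.dice_voxel_mm)
                    if cfg.compute_dice else np.nan,
                })
    semi_pairwise = pd.DataFrame(rows)

    rows = []
    for (p, e, _, s), rec in semi.items():
        if s != 1:
            continue
        first = semi.get((p, e, "semi_auto", 0))
        if first is None:
            continue
        rows.append({"patient": p, "expert": e,
                     "asd": asd_mesh_to_mesh(rec.mesh, first.mesh)})
    semi_intra = pd.DataFrame(rows)

    # ---- stage 6: leave-one-out STAPLE consensus --------------------------
    rows = []
    consensus_all: dict[str, object] = {}
    for p in patients:
        keys = sorted(k for k in semi if k[0] == p and k[3] == 0)
        meshes = [semi[k].mesh for k in keys]
        if len(meshes) >= 2:
            consensus_all[p] = staple_mesh_consensus(
                meshes, tol_mm=cfg.consensus_tol_mm,
                max_iter=cfg.consensus_max_iter).consensus
        if len(meshes) < 3:
            continue
        for i, k in enumerate(keys):
            others = [m for j, m in enumerate(meshes) if j != i]
            cons = staple_mesh_consensus(
                others, tol_mm=cfg.consensus_tol_mm,
                max_iter=cfg.consensus_max_iter).consensus
            rows.append({
                "patient": p, "expert": k[1],
                "asd": asd_mesh_to_mesh(semi[k].mesh, cons),
                "hausdorff": hausdorff(semi[k].mesh, cons),
                "dice": dice_meshes(semi[k].mesh, cons, cfg.dice_voxel_mm)
                if cfg.compute_dice else np.nan,
            })
    semi_staple = pd.DataFrame(rows)

    # ---- stage 7: manual vs semi-auto (+ per-point records for maps) ------
    rows, cons_rows = [], []
    per_point: list[tuple] = []   # (annotation key, per-point distances)
    for (p, e, _, s), entry in recon.items():
        if s != 0:
            continue
        pts = entry["annotation"].all_points()
        for k, rec in semi.items():
            if k[0] != p or k[3] != 0 or k[1] == e:
                continue
            rows.append({"patient": p, "expert_manual": e,
                         "expert_semi": k[1],
                         "asd": asd_points_to_mesh(pts, rec.mesh)})
        cons = consensus_all.get(p)
        if cons is not None:
            d = closest_point_on_mesh(pts, cons).distances
            cons_rows.append({"patient": p, "expert_manual": e,
                              "asd": float(d.mean())})
            per_point.append(((p, e), entry["annotation"], d))
    manual_vs_semi = pd.DataFrame(rows)
    manual_vs_cons = pd.DataFrame(cons_rows)

    # ---- stage 8: statistics on the three manual contrasts ----------------
    tests: dict[str, GroupComparison] = {}

    def _paired(df: pd.DataFrame, unit_cols: list[str]):
        wide = df.pivot_table(index=unit_cols, columns="method",
                              values="asd")
        wide = wide.dropna()
        return wide["manual_SSM"].to_numpy(), \
            wide["manual_soft_SSM"].to_numpy()

    if len(manual_inter):
        x, y = _paired(manual_inter,
                       ["patient", "expert_points", "expert_mesh"])
        if len(x) >= 3:
            tests["inter_ssm_vs_softssm"] = compare_groups(x, y, paired=True)
    if len(manual_intra):
        x, y = _paired(manual_intra, ["patient", "expert"])
        if len(x) >= 3:
            tests["intra_ssm_vs_softssm"] = compare_groups(x, y, paired=True)
    if len(method_impact):
        x, y = _paired(method_impact, ["patient", "expert", "session"])
        if len(x) >= 3:
            tests["fidelity_ssm_vs_softssm"] = compare_groups(
                x, y, paired=True)

    # ---- stage 9: spatial maps --------------------------------------------
    maps: dict[str, SurfaceMap] = {}
    rho = float("nan")
    if per_point:
        mapped_pts, values = [], []
        for (_, _), ann, dists in per_point:
            mp = register_annotation_to_reference(ann, ssm)
            # landmarks prepend all_points(); contour values only
            mapped_pts.append(mp.points)
            values.append(dists[3:] if len(dists) == ann.n_points + 3
                          else dists)
        allp = np.vstack(mapped_pts)
        allv = np.concatenate(values)
        from .spatial import MappedPoints
        merged = MappedPoints(allp, np.empty(0), np.empty(0), np.empty(0))
        maps["density"] = surface_density_map(ssm, merged,
                                              cfg.map_bandwidth_mm)
        maps["asd"] = surface_asd_map(ssm, merged, allv,
                                      cfg.map_bandwidth_mm)
        rho = density_asd_rank_correlation(maps["density"], maps["asd"])

    # ---- summaries, audit, output -----------------------------------------
    tables = {
        "manual_inter": manual_inter,
        "manual_intra": manual_intra,
        "method_impact": method_impact,
        "semiauto_pairwise": semi_pairwise,
        "semiauto_intra": semi_intra,
        "semiauto_staple": semi_staple,
        "manual_vs_semiauto": manual_vs_semi,
        "manual_vs_consensus": manual_vs_cons,
    }
    summaries: dict[str, MetricSummary] = {}
    for m in methods:
        sel = manual_inter[manual_inter["method"] == m]["asd"]
        if len(sel):
            summaries[f"manual_inter_{m}"] = summarize(
                sel, f"manual inter ASD {m}")
        sel = manual_intra[manual_intra["method"] == m]["asd"] \
            if len(manual_intra) else []
        if len(sel):
            summaries[f"manual_intra_{m}"] = summarize(
                sel, f"manual intra ASD {m}")
        sel = method_impact[method_impact["method"] == m]["asd"]
        if len(sel):
            summaries[f"fidelity_{m}"] = summarize(sel, f"fidelity ASD {m}")
    for name, df, col in (
            ("semiauto_pairwise_asd", semi_pairwise, "asd"),
            ("semiauto_pairwise_dice", semi_pairwise, "dice"),
            ("semiauto_pairwise_hausdorff", semi_pairwise, "hausdorff"),
            ("semiauto_staple_asd", semi_staple, "asd"),
            ("semiauto_staple_dice", semi_staple, "dice"),
            ("semiauto_staple_hausdorff", semi_staple, "hausdorff"),
            ("semiauto_intra_asd", semi_intra, "asd"),
            ("manual_vs_semiauto_asd", manual_vs_semi, "asd"),
            ("manual_vs_consensus_asd", manual_vs_cons, "asd")):
        if len(df) and col in df and df[col].notna().any():
            summaries[name] = summarize(df[col].dropna(), name)

    audit = audit_counts(cohort, tables)
    return StudyResults(tables, summaries, tests,
                        cross_study_effect_sizes(), maps, rho, audit)


def audit_counts(cohort: CohortData, tables: dict[str, pd.DataFrame]) -> dict:
    """Check each comparison table's row count against the arithmetic implied
    by the cohort manifest (every applicable session pair exactly once)."""
    sessions = [(r.annotation.patient_id, r.annotation.expert_id,
                 r.annotation.method, r.annotation.session)
                for r in cohort.records]
    patients = sorted({s[0] for s in sessions})
    expected = {}
    n_inter = n_intra = n_pair = n_staple = n_mvs = 0
    for p in patients:
        man0 = [s for s in sessions if s[0] == p and s[2] == "manual"
                and s[3] == 0]
        man1 = [s for s in sessions if s[0] == p and s[2] == "manual"
                and s[3] == 1]
        sa0 = [s for s in sessions if s[0] == p and s[2] == "semi_auto"
               and s[3] == 0]
        n_inter += len(man0) * (len(man0) - 1) * 2       # ordered pairs x 2 methods
        n_intra += sum(2 * 2 for s in man1
                       if (p, s[1], "manual", 0) in sessions)
        n_pair += len(sa0) * (len(sa0) - 1) // 2
        if len(sa0) >= 3:
            n_staple += len(sa0)
        # per manual session-0: every other-expert semi-auto session-0 mesh
        for m in man0:
            n_mvs += sum(1 for s in sa0 if s[1] != m[1])
    expected["manual_inter"] = n_inter
    expected["manual_intra"] = n_intra
    expected["semiauto_pairwise"] = n_pair
    expected["semiauto_staple"] = n_staple
    expected["manual_vs_semiauto"] = n_mvs
    expected["method_impact"] = 2 * len(
        [s for s in sessions if s[2] == "manual"])
    observed = {k: len(tables[k]) for k in expected}
    return {"expected": expected, "observed": observed,
            "consistent": expected == observed}


def reproduce_effect_size_table(fixture_path: str | Path | None = None
                                ) -> pd.DataFrame:
    """Cross-study Cohen's d table from published summary statistics."""
    if fixture_path is None:
        return cross_study_effect_sizes()
    df = pd.read_csv(fixture_path, keep_default_na=False)
    for col in ("center", "sd", "iqr_low", "iqr_high"):
        if col not in df.columns:
            raise GeometryError(f"fixture missing column {col!r}")
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return cross_study_effect_sizes(df)


def write_study_results(results: StudyResults, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in results.tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    results.effect_sizes.to_csv(out / "effect_sizes.csv", index=False)
    for name, smap in results.maps.items():
        smap.to_frame().to_csv(out / f"map_{name}.csv", index=False)
    summary = {
        "summaries": {k: {"median": v.median, "iqr_low": v.iqr_low,
                          "iqr_high": v.iqr_high, "n": v.n}
                      for k, v in results.summaries.items()},
        "tests": {k: {"test": t.test, "statistic": t.statistic,
                      "p": t.p_value, "p_adjusted": t.p_adjusted}
                  for k, t in results.tests.items()},
        "density_asd_rank_correlation": results.density_asd_rho,
        "audit": results.audit,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return out
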