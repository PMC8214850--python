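"""End-to-end analysis orchestration.

Runs the full garden-hunting analysis from raw tables (real CSVs or a
simulated preset) to a machine-readable report: event collapsing and
detection summaries, site filtering, detection histories, per-species
Royle-Nichols full-model fit with bootstrap goodness of fit, candidate-set
ranking with (Q)AICc, variable importance and conditional model averaging,
model-averaged abundance predictions compared between hunted and unhunted
sites, interview indexes, and the hunting-selection regressions.

All randomness flows from one master seed; running the same configuration
twice produces an identical ``report.json``.  Outputs are written per stage
so every number in the report traces to a CSV on disk, and a manifest
records the seed, package versions and output file hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ethno import indices_table, read_interviews, tally_citations
from .hunting import chi2_contingency, compare_lambda_by_hunting, fit_hunting_glm
from .modelsel import (
    ModelTable,
    fit_candidate_set,
    gof_bootstrap,
    model_average,
    variable_importance,
)
from .rn import DETECTION_TERMS, RNSpec, fit_rn, predict_lambda
from .simulate import SyntheticTruth, default_truth, simulate_study
from .survey import (
    build_histories,
    collapse_events,
    filter_sites,
    frequency_of_detection,
    history_to_frame,
    read_deployments,
    read_photos,
    read_tracks,
    standardize,
    subset_history,
    tabulate_detections,
    track_density,
)

log = logging.getLogger("gardenhunt")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline settings; defaults reproduce the study's stated choices
    (21-day visits, 7-day activity and 5-km conuco filters, 10,000 bootstrap
    samples, averaging over Delta(Q)AICc <= 10, >10-detection inclusion)."""

    out_dir: str = "runs/latest"
    seed: int = 1
    # inputs: either a simulation preset or CSV paths
    preset: str | None = None           # "gran-sabana"
    photos: str | None = None
    deployments: str | None = None
    covariates: str | None = None
    tracks: str | None = None
    interviews: str | None = None
    taxonomy_map: str | None = None
    # survey construction
    season_start: str = "2015-09-21"
    season_days: int = 180
    period_days: int = 60
    visit_days: int = 21
    min_active_days: float = 7
    max_dist_conuco_m: float = 5000.0
    # modelling
    detection_threshold: int = 10
    quadratic_species: list[str] = field(default_factory=list)
    boot_samples: int = 10000
    delta_max: float = 10.0
    n_starts: int = 3
    truncation_K: int | None = None

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _stage(name):
    log.info("stage: %s", name)
    return name


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else round(v, 6)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if obj is pd.NA or (isinstance(obj, float) and pd.isna(obj)):
        return None
    return obj


def _load_inputs(cfg: RunConfig, out: Path):
    if cfg.preset is not None:
        if cfg.preset != "gran-sabana":
            raise ValueError(f"unknown preset {cfg.preset!r}")
        truth = default_truth(seed=cfg.seed)
        tables = simulate_study(truth)
        truth.to_json(out / "truth.json")
        for name in ("covariates", "tracks", "photos", "deployments", "interviews"):
            tables[name].to_csv(out / f"{name}.csv", index=False)
        deps = _deployments_from_frame(tables["deployments"])
        return (tables["photos"], deps, tables["covariates"], tables["tracks"],
                tables["interviews"], truth.taxonomy_map)
    for key in ("photos", "deployments", "covariates"):
        path = getattr(cfg, key)
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"stage inputs: missing {key} file: {path}")
    photos = read_photos(cfg.photos)
    deps = read_deployments(cfg.deployments)
    covariates = pd.read_csv(cfg.covariates, dtype={"camera_id": str})
    tracks = read_tracks(cfg.tracks) if cfg.tracks else None
    interviews = read_interviews(cfg.interviews) if cfg.interviews else None
    tmap = None
    if cfg.taxonomy_map:
        m = pd.read_csv(cfg.taxonomy_map)
        tmap = dict(zip(m["vernacular"], m["taxon"]))
    return photos, deps, covariates, tracks, interviews, tmap


def _deployments_from_frame(df: pd.DataFrame):
    from .survey import Deployment

    deps = {}
    for _, row in df.iterrows():
        cam = str(row["camera_id"])
        if cam not in deps:
            deps[cam] = Deployment(cam, float(row["x"]), float(row["y"]),
                                   str(row.get("block", "")))
        deps[cam].activity_intervals.append(
            (pd.Timestamp(row["start"]), pd.Timestamp(row["end"]))
        )
    for d in deps.values():
        d.activity_intervals.sort()
    return list(deps.values())


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and return the report dict (also written as JSON)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _json_safe(asdict(cfg))}

    stage = _stage("load-inputs")
    try:
        photos, deps, covariates, tracks, interviews, tmap = _load_inputs(cfg, out)

        stage = _stage("detection-events")
        events = collapse_events(photos)
        D, _ = tabulate_detections(events)
        camera_days = sum(d.active_days() for d in deps)
        report["survey"] = {
            "n_events": int(D.sum()),
            "camera_days": round(camera_days, 2),
            "species": {
                sp: {"D": int(d),
                     "FD": frequency_of_detection(int(d), camera_days)}
                for sp, d in D.items()
            },
        }

        stage = _stage("site-filter")
        retained, exclusions = filter_sites(
            covariates, deps, cfg.min_active_days, cfg.max_dist_conuco_m
        )
        exclusions.to_csv(out / "exclusions.csv", index=False)
        report["sites"] = {"retained": len(retained),
                           "excluded": len(exclusions)}

        stage = _stage("detection-histories")
        histories = build_histories(
            events, deps, cfg.season_start, cfg.visit_days,
            cfg.season_days, cfg.period_days,
        )
        histories = {sp: subset_history(h, retained)
                     for sp, h in histories.items()}
        for sp, h in histories.items():
            history_to_frame(h).to_csv(out / f"history_{sp}.csv", na_rep="NA")

        stage = _stage("covariates")
        cov = covariates.set_index("camera_id").loc[retained].reset_index()
        if "track_dens" not in cov.columns:
            if tracks is None:
                raise FileNotFoundError("stage covariates: missing tracks file")
            xy = covariates.set_index("camera_id")
            cov["track_dens"] = [
                track_density((xy.loc[c, "x"], xy.loc[c, "y"]), tracks)
                for c in retained
            ]
        cov_std = cov.copy()
        for c in ("tree_buffer", "dist_river", "dist_conuco", "track_dens"):
            cov_std[c] = standardize(cov_std[c].to_numpy(float))

        stage = _stage("fit-select")
        report["models"] = {}
        lambda_rows = {}
        for i_sp, (sp, h) in enumerate(sorted(histories.items())):
            if h.total_detections <= cfg.detection_threshold:
                continue
            quad = sp in cfg.quadratic_species
            full = RNSpec(
                species=sp,
                detection_terms=DETECTION_TERMS,
                site_terms=("tree_buffer",) + (("tree_buffer2",) if quad else ())
                + ("dist_river", "dist_conuco"),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                full_fit = fit_rn(full, h, cov_std, K=cfg.truncation_K,
                                  n_starts=cfg.n_starts, seed=cfg.seed + i_sp)
            entry: dict = {"total_detections": h.total_detections,
                           "full_model_converged": full_fit.converged}
            if not full_fit.converged:
                report["models"][sp] = entry
                continue
            gof = gof_bootstrap(full_fit, B=cfg.boot_samples,
                                seed=cfg.seed + 1000 + i_sp)
            entry["gof"] = {"chi2": gof.chi2_obs, "p": gof.p_value,
                            "c_hat": gof.c_hat}
            mt = fit_candidate_set(
                h, cov_std, species=sp, allow_quadratic=quad,
                c_hat=gof.c_hat, K=cfg.truncation_K,
                n_starts=cfg.n_starts, seed=cfg.seed + i_sp,
            )
            mt.table.to_csv(out / f"model_table_{sp}.csv", index=False)
            entry["criterion"] = mt.criterion
            entry["table_head"] = mt.table.head(5).to_dict("records")
            entry["importance"] = {
                term: dict(zip(("sum_of_weights", "support"),
                               variable_importance(mt, term)))
                for term in ("effort", "date", "tracks_dens", "tree_buffer",
                             "dist_river", "dist_conuco")
            }
            avg = model_average(mt, delta_max=cfg.delta_max)
            avg.to_csv(out / f"averaged_coefs_{sp}.csv", index=False)
            entry["averaged_coefs"] = avg.to_dict("records")

            keep = mt.table["delta"].to_numpy() <= cfg.delta_max
            w = mt.table["weight"].to_numpy()[keep]
            w = w / w.sum()
            lam = np.zeros(len(retained))
            for f, wi in zip(
                [f for f, k in zip(mt.fits, keep) if k], w
            ):
                lam += wi * predict_lambda(f, cov_std)["lambda"].to_numpy()
            lambda_rows[sp] = lam
            entry["lambda_by_hunting"] = compare_lambda_by_hunting(
                lam, cov["hunting"].to_numpy(bool)
            )
            report["models"][sp] = entry
        if lambda_rows:
            pd.DataFrame(lambda_rows, index=pd.Index(retained, name="camera_id")
                         ).to_csv(out / "lambda_predictions.csv")

        stage = _stage("ethno-indices")
        if interviews is not None:
            counts = tally_citations(interviews, tmap)
            idx = indices_table(counts)
            idx.to_csv(out / "indices.csv", index=False)
            report["indices"] = {
                "N": counts.N, "n": counts.n, "N_pref": counts.N_pref,
                "table": idx.to_dict("records"),
            }

        stage = _stage("hunting-selection")
        if "hunting" in cov.columns:
            glm = fit_hunting_glm(cov)
            glm.to_frame().to_csv(out / "glm.csv")
            report["hunting_glm"] = {
                "coef": glm.to_frame().to_dict("index"),
                "null_deviance": glm.null_deviance,
                "deviance": glm.deviance,
                "aic": glm.aic,
                "n": glm.n,
            }
        if interviews is not None:
            chi2_out = {}
            for what, col, levels in (
                ("habitat", "habitat_pref", ["forest", "savanna", "mixed"]),
                ("season", "season_pref", ["all year", "rainy", "none"]),
            ):
                tab = pd.crosstab(interviews["community"], interviews[col])
                tab = tab.reindex(columns=levels, fill_value=0)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = chi2_contingency(tab)
                chi2_out[what] = {"chi2": res.chi2, "df": res.df, "p": res.p}
            pd.DataFrame(chi2_out).T.to_csv(out / "chi2.csv")
            report["preference_chi2"] = chi2_out
    except Exception as exc:
        (out / "report.json").write_text(
            json.dumps(_json_safe(report), indent=2, sort_keys=True)
        )
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    report_text = json.dumps(_json_safe(report), indent=2, sort_keys=True)
    (out / "report.json").write_text(report_text)

    manifest = {
        "seed": cfg.seed,
        "gardenhunt": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "files": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(out.glob("*.csv")) + [out / "report.json"]
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return report
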