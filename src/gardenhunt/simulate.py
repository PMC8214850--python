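"""Synthetic Gran-Sabana-style studies with known truth.

Generates complete, internally consistent inputs for every pipeline stage —
landscape covariates, camera deployments, photo records produced by the
Royle-Nichols detection process, off-camera track records, and interview
tables — from a serializable :class:`SyntheticTruth` so that estimators can
be scored against the generating parameters.

The default truth mirrors the savanna-forest camera-trap study design this
package targets: 60 cameras in six blocks sampled over three 60-day periods
(about 54 surviving the distance/activity filters), up to nine 21-day
visits, bimodal tree cover with a savanna mode at 10-20% and a forest mode
at 70-80%, distance-to-conuco with mean ~1.58 km truncated at 8 km, 159
off-camera track records, and 29 interview respondents from four
communities.  Species coefficients are on the link scales (logit for
per-individual detection, log for expected abundance) with site covariates
standardized.

Everything is driven by a single integer seed; regenerating from the same
truth is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rn import RNSpec, build_design, simulate_y
from .survey import DetectionHistory, standardize, track_density, visit_windows

__all__ = [
    "SyntheticTruth",
    "default_truth",
    "simulate_landscape",
    "simulate_rn_survey",
    "simulate_interviews",
    "simulate_study",
    "simulate_species_history",
]

COMMUNITIES = {"Wuarapata": 11, "Uroy-Uaray": 8, "Kawi": 5, "Mare-Paru": 5}


@dataclass
class SyntheticTruth:
    """Generator parameters; fully serializable for recovery scoring."""

    seed: int = 0
    # survey design
    n_cameras: int = 60
    n_blocks: int = 6
    season_start: str = "2015-09-21"
    season_days: int = 180
    period_days: int = 60
    visit_days: int = 21
    n_always_on: int = 18        # cameras kept in place all three periods
    p_visit_absent: float = 0.08
    p_visit_partial: float = 0.15
    n_short_activity: int = 2    # cameras failing within a week (filtered out)
    # landscape
    block_size_m: float = 7000.0
    tree_modes: tuple = ((15.0, 4.0), (75.0, 6.0))
    tree_weights: tuple = (0.5, 0.5)
    conuco_dist_logmean: float = 6.865  # lognormal: mean ~1.58 km
    conuco_dist_logsd: float = 1.0
    conuco_dist_max: float = 8000.0
    river_dist_logmean: float = 6.3
    river_dist_logsd: float = 0.8
    n_tracks: int = 159
    track_scatter_m: float = 300.0
    # hunting-occurrence process (raw-scale logistic coefficients)
    hunting_coefs: dict = field(
        default_factory=lambda: {
            "intercept": -1.475,
            "tree_buffer": 0.041,
            "dist_river": 0.001,
            "dist_conuco": -0.0001,
        }
    )
    # species processes: link-scale coefficients on standardized covariates
    species: dict = field(
        default_factory=lambda: {
            "cuniculus": {
                "alpha": {"intercept": -1.0, "effort": 0.5},
                "beta": {"intercept": 0.7, "tree_buffer": 0.3, "dist_conuco": -0.5},
            },
            "dasyprocta": {
                "alpha": {"intercept": -1.0, "effort": 0.5},
                "beta": {"intercept": 0.5, "tree_buffer": 1.0},
            },
            "crax": {
                "alpha": {"intercept": -1.2, "effort": 0.5},
                "beta": {"intercept": 0.3, "tree_buffer": 0.8, "dist_conuco": -0.4},
            },
            "cerdocyon": {
                "alpha": {"intercept": -1.5},
                "beta": {"intercept": 0.3},
            },
        }
    )
    # interviews
    n_respondents: int = 29
    communities: dict = field(default_factory=lambda: dict(COMMUNITIES))
    n_hunters: int = 24          # active + inactive; only they cite game
    citation_probs: dict = field(
        default_factory=lambda: {
            "uraná": 0.20,      # lowland paca
            "waikín": 0.16,     # white-tailed deer
            "pauwi": 0.14,      # black curassow
            "maikuri": 0.10,    # tapir
            "akuri": 0.10,      # agouti
            "forest deer": 0.06,
            "savanna deer": 0.06,
            "pakirá": 0.06,     # white-lipped peccary
            "marú": 0.07,       # great tinamou
            "wora": 0.05,       # guan
        }
    )
    preference_weights: dict = field(
        default_factory=lambda: {"waikín": 0.5, "uraná": 0.3, "pauwi": 0.2}
    )
    preference_fallback_weight: float = 0.02
    p_no_preference: float = 0.2
    citations_min: int = 3
    citations_max: int = 6
    taxonomy_map: dict = field(
        default_factory=lambda: {
            "uraná": "Cuniculus",
            "waikín": "Odocoileus",
            "pauwi": "Crax",
            "maikuri": "Tapirus",
            "akuri": "Dasyprocta",
            "forest deer": "Mazama",
            "savanna deer": "Mazama",
            "pakirá": "Tayassu",
            "marú": "Tinamus",
            "wora": "Penelope",
        }
    )

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, ensure_ascii=False)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "SyntheticTruth":
        try:
            data = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path, encoding="utf-8") as fh:
                data = json.load(fh)
        for key in ("tree_modes", "tree_weights"):
            if key in data:
                data[key] = tuple(
                    tuple(v) if isinstance(v, list) else v for v in data[key]
                )
        return cls(**data)


def default_truth(seed: int = 0, **overrides) -> SyntheticTruth:
    """The preset study-scale truth with a chosen seed."""
    return SyntheticTruth(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# landscape


def _truncated_lognormal(rng, logmean, logsd, upper, size) -> np.ndarray:
    out = rng.lognormal(logmean, logsd, size)
    for _ in range(100):
        bad = out > upper
        if not bad.any():
            break
        out[bad] = rng.lognormal(logmean, logsd, bad.sum())
    return np.minimum(out, upper)


def simulate_landscape(
    truth: SyntheticTruth, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Site covariates and off-camera track records.

    Tree cover comes from a two-component normal mixture truncated to
    [0, 100] (savanna and forest modes); conuco and river distances from
    lognormals calibrated to the target mean/range; the hunting flag from a
    raw-scale logistic process; track records are scattered around
    forest-leaning sites so the inverse-distance density covariate carries
    signal.  Returns ``(covariates, tracks)``; the ``track_dens`` column is
    the raw inverse-distance sum (standardize before modelling).
    """
    M = truth.n_cameras
    per_block = M // truth.n_blocks
    ids = [f"B{b + 1:02d}-C{c + 1:02d}" for b in range(truth.n_blocks)
           for c in range(per_block)]
    bx = np.repeat(np.arange(truth.n_blocks) % 3, per_block) * truth.block_size_m * 1.2
    by = np.repeat(np.arange(truth.n_blocks) // 3, per_block) * truth.block_size_m * 1.2
    x = bx + rng.uniform(0, truth.block_size_m, M)
    y = by + rng.uniform(0, truth.block_size_m, M)

    comp = rng.choice(len(truth.tree_weights), size=M, p=np.asarray(truth.tree_weights))
    mus = np.array([m for m, _ in truth.tree_modes])
    sds = np.array([s for _, s in truth.tree_modes])
    tree = np.clip(rng.normal(mus[comp], sds[comp]), 0.0, 100.0)

    dist_conuco = _truncated_lognormal(
        rng, truth.conuco_dist_logmean, truth.conuco_dist_logsd,
        truth.conuco_dist_max, M,
    )
    dist_river = rng.lognormal(truth.river_dist_logmean, truth.river_dist_logsd, M)

    hc = truth.hunting_coefs
    eta = (hc["intercept"] + hc["tree_buffer"] * tree
           + hc["dist_river"] * dist_river + hc["dist_conuco"] * dist_conuco)
    hunting = rng.random(M) < 1.0 / (1.0 + np.exp(-eta))

    # tracks cluster near high-cover sites
    w = tree + 5.0
    anchor = rng.choice(M, size=truth.n_tracks, p=w / w.sum())
    tx = x[anchor] + rng.normal(0, truth.track_scatter_m, truth.n_tracks)
    ty = y[anchor] + rng.normal(0, truth.track_scatter_m, truth.n_tracks)
    t0 = pd.Timestamp(truth.season_start)
    tracks = pd.DataFrame(
        {
            "x": tx,
            "y": ty,
            "date": [
                (t0 + pd.Timedelta(days=int(d))).date().isoformat()
                for d in rng.integers(0, truth.season_days, truth.n_tracks)
            ],
            "note": "field sign",
        }
    )

    dens = [track_density((xi, yi), tracks) for xi, yi in zip(x, y)]
    covariates = pd.DataFrame(
        {
            "camera_id": ids,
            "x": x,
            "y": y,
            "tree_buffer": tree,
            "dist_river": dist_river,
            "dist_conuco": dist_conuco,
            "track_dens": dens,
            "hunting": hunting,
        }
    )
    return covariates, tracks


# ---------------------------------------------------------------------------
# camera survey


def _activity_schedule(truth: SyntheticTruth, rng) -> tuple[np.ndarray, np.ndarray]:
    """Per camera-visit active day counts and the per-camera period sets.

    The first ``n_always_on`` cameras stay for all periods (three cameras
    per block in the default design); the rest are split evenly across
    single periods.  Within an active period a visit may be knocked out
    entirely or covered only partially (camera failure, service gaps).
    """
    M = truth.n_cameras
    windows = visit_windows(truth.visit_days, truth.season_days, truth.period_days)
    J = len(windows)
    per_period = (M - truth.n_always_on) // 3
    periods = []
    for i in range(M):
        if i < truth.n_always_on:
            periods.append({0, 1, 2})
        else:
            periods.append({min((i - truth.n_always_on) // per_period, 2)})
    active = np.zeros((M, J))
    for i in range(M):
        for j, (a, b) in enumerate(windows):
            if int(a // truth.period_days) not in periods[i]:
                continue
            wl = b - a
            u = rng.random()
            if u < truth.p_visit_absent:
                continue
            if u < truth.p_visit_absent + truth.p_visit_partial:
                active[i, j] = rng.integers(1, int(wl))
            else:
                active[i, j] = wl
    # a couple of cameras fail within days of deployment (site filter food)
    for i in rng.choice(M, size=truth.n_short_activity, replace=False):
        active[i] = 0.0
        j0 = next(
            j for j, (a, _) in enumerate(windows)
            if int(a // truth.period_days) in periods[i]
        )
        active[i, j0] = rng.integers(2, 6)
    return active, np.array([sorted(p) for p in periods], dtype=object)


def simulate_rn_survey(
    truth: SyntheticTruth,
    covariates: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Photo records and deployments from the latent-abundance process.

    Per species: ``N_i ~ Poisson(exp(x_i . beta))`` on standardized site
    covariates; each visit detects with ``p = 1 - (1 - r_ij)^{N_i}`` where
    ``logit r_ij`` uses the realized effort, standardized visit date, and
    standardized track density; a detected camera-visit emits 1-3 photo
    timestamps inside the camera's active span of that visit.
    """
    season_start = pd.Timestamp(truth.season_start)
    windows = visit_windows(truth.visit_days, truth.season_days, truth.period_days)
    J = len(windows)
    M = truth.n_cameras
    lengths = np.array([b - a for a, b in windows])

    active, _ = _activity_schedule(truth, rng)
    effort = np.where(active > 0, active / lengths[None, :], np.nan)

    std = covariates.copy()
    for c in ("tree_buffer", "dist_river", "dist_conuco", "track_dens"):
        std[c] = standardize(std[c].to_numpy())
    date = np.tile(standardize(np.array([a for a, _ in windows])), (M, 1))

    dep_rows = []
    per_block = M // truth.n_blocks
    for i, cam in enumerate(covariates["camera_id"]):
        spans = _contiguous_spans(active[i], windows)
        for a, b in spans:
            dep_rows.append(
                {
                    "camera_id": cam,
                    "x": covariates["x"].iloc[i],
                    "y": covariates["y"].iloc[i],
                    "block": f"B{i // per_block + 1:02d}",
                    "start": (season_start + pd.Timedelta(days=a)).isoformat(),
                    "end": (season_start + pd.Timedelta(days=b)).isoformat(),
                }
            )
    deployments = pd.DataFrame(dep_rows)

    photo_rows = []
    sites = list(covariates["camera_id"])
    for sp, pars in truth.species.items():
        spec, alpha, beta = _spec_from_coefs(sp, pars)
        hist = DetectionHistory(
            species=sp, sites=sites, windows=windows,
            y=np.where(np.isnan(effort), np.nan, 0.0),
            effort=effort, date=date,
        )
        design = build_design(spec, hist, std.drop(columns=["x", "y", "hunting"]))
        ysim = simulate_y(rng, alpha, beta, design)
        for i, j in zip(*np.nonzero(ysim == 1.0)):
            a = windows[j][0]
            span = active[i, j]
            for _ in range(int(rng.integers(1, 4))):
                offset_days = span * rng.random()
                t = season_start + pd.Timedelta(days=float(a) + float(offset_days))
                photo_rows.append(
                    {
                        "camera_id": sites[i],
                        "species": sp,
                        "timestamp": t.floor("min").isoformat(),
                    }
                )
    photos = pd.DataFrame(photo_rows, columns=["camera_id", "species", "timestamp"])
    photos = photos.sort_values(["camera_id", "species", "timestamp"]).reset_index(
        drop=True
    )
    return photos, deployments


def _contiguous_spans(active_row, windows) -> list[tuple[float, float]]:
    """Day-offset activity spans: each active visit contributes its first
    ``active`` days, merged across adjacent fully active visits."""
    spans = []
    for j, (a, b) in enumerate(windows):
        d = float(active_row[j])
        if d <= 0:
            continue
        spans.append((a, a + d))
    merged: list[list[float]] = []
    for s, e in spans:
        if merged and abs(merged[-1][1] - s) < 1e-9:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _spec_from_coefs(name: str, pars: dict) -> tuple[RNSpec, np.ndarray, np.ndarray]:
    det = tuple(t for t in ("date", "effort", "tracks_dens") if t in pars["alpha"])
    site = tuple(
        t for t in ("tree_buffer", "tree_buffer2", "dist_river", "dist_conuco")
        if t in pars["beta"]
    )
    spec = RNSpec(species=name, detection_terms=det, site_terms=site)
    alpha = np.array([pars["alpha"].get("intercept", 0.0)]
                     + [pars["alpha"][t] for t in det])
    beta = np.array([pars["beta"].get("intercept", 0.0)]
                    + [pars["beta"][t] for t in site])
    return spec, alpha, beta


def simulate_species_history(
    covariates: pd.DataFrame,
    alpha_coefs: dict,
    beta_coefs: dict,
    rng: np.random.Generator,
    n_visits: int = 9,
    visit_days: int = 21,
    p_missing: float = 0.1,
    p_partial: float = 0.15,
    species: str = "sim",
) -> tuple[DetectionHistory, RNSpec]:
    """Draw one species' detection history directly at the matrix level.

    A fast path for estimator-recovery experiments: skips the photo /
    deployment round trip (exercised elsewhere) and produces the
    DetectionHistory the fitters consume.  A ``p_missing`` fraction of
    camera-visits is knocked out entirely and a further ``p_partial``
    fraction gets partial effort, as camera failures produce in the field.
    """
    M = len(covariates)
    windows = [
        (float(visit_days * j), float(visit_days * (j + 1))) for j in range(n_visits)
    ]
    u = rng.random((M, n_visits))
    mask = u < p_missing
    effort = np.where(mask, np.nan, 1.0)
    partial = (u >= p_missing) & (u < p_missing + p_partial)
    effort[partial] = np.round(
        rng.integers(1, visit_days, partial.sum()) / visit_days, 6
    )
    date_row = (
        standardize(np.arange(n_visits)) if n_visits > 1 else np.zeros(1)
    )
    date = np.tile(date_row, (M, 1))
    hist = DetectionHistory(
        species=species,
        sites=list(covariates["camera_id"]),
        windows=windows,
        y=np.where(mask, np.nan, 0.0),
        effort=effort,
        date=date,
    )
    spec, alpha, beta = _spec_from_coefs(
        species, {"alpha": alpha_coefs, "beta": beta_coefs}
    )
    design = build_design(spec, hist, covariates)
    hist.y = simulate_y(rng, alpha, beta, design)
    return hist, spec


# ---------------------------------------------------------------------------
# interviews


def simulate_interviews(truth: SyntheticTruth, rng: np.random.Generator) -> pd.DataFrame:
    """Interview table: citations, ranked preferences, habitat/season."""
    rows = []
    comm = [c for c, k in truth.communities.items() for _ in range(k)]
    n = truth.n_respondents
    comm = (comm * (n // max(len(comm), 1) + 1))[:n]
    taxa = list(truth.citation_probs)
    probs = np.array([truth.citation_probs[t] for t in taxa])
    probs = probs / probs.sum()
    pref_w = truth.preference_weights
    n_inactive = min(5, truth.n_hunters)
    statuses = (["active"] * (truth.n_hunters - n_inactive)
                + ["inactive"] * n_inactive
                + ["non-hunter"] * max(n - truth.n_hunters, 0))
    statuses = statuses[:n]
    for idx in range(n):
        status = statuses[idx]
        cited: list[str] = []
        prefs: list[str] = []
        if status != "non-hunter":
            k = int(rng.integers(truth.citations_min, truth.citations_max + 1))
            cited = list(rng.choice(taxa, size=min(k, len(taxa)),
                                    replace=False, p=probs))
            if rng.random() > truth.p_no_preference:
                w = np.array([pref_w.get(t, truth.preference_fallback_weight)
                              for t in cited])
                n_rankable = int((w > 0).sum())
                if n_rankable:
                    order = list(rng.choice(len(cited),
                                            size=min(3, n_rankable),
                                            replace=False, p=w / w.sum()))
                    prefs = [cited[i] for i in order]
        rows.append(
            {
                "respondent_id": f"R{idx + 1:02d}",
                "community": comm[idx],
                "age": int(rng.integers(22, 71)),
                "gender": "f" if idx < 3 else "m",
                "hunter_status": status,
                "cited_taxa": ";".join(cited),
                "ranked_preferences": ";".join(prefs),
                "habitat_pref": rng.choice(
                    ["forest", "savanna", "mixed"], p=[0.55, 0.2, 0.25]
                ),
                "season_pref": rng.choice(
                    ["all year", "rainy", "none"], p=[0.2, 0.65, 0.15]
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# one-call study


def simulate_study(truth: SyntheticTruth) -> dict[str, pd.DataFrame]:
    """Generate a full study: covariates, tracks, photos, deployments,
    interviews.  Deterministic in ``truth.seed``."""
    rng = np.random.default_rng(truth.seed)
    covariates, tracks = simulate_landscape(truth, rng)
    photos, deployments = simulate_rn_survey(truth, covariates, rng)
    interviews = simulate_interviews(truth, rng)
    return {
        "covariates": covariates.drop(columns=["x", "y"]).assign(
            camera_id=covariates["camera_id"]
        )[["camera_id", "tree_buffer", "dist_river", "dist_conuco",
           "track_dens", "hunting"]],
        "site_coords": covariates[["camera_id", "x", "y"]],
        "tracks": tracks,
        "photos": photos,
        "deployments": deployments,
        "interviews": interviews,
    }
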