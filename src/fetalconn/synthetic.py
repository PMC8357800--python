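"""Synthetic cohort generator.

Emulates the statistical structure that the downstream analysis chain
assumes: five stress/negative-affect scales loading on one latent factor
(NAS), per-subject ROI timeseries drawn from a block-structured correlation
matrix with planted functional networks, a designated set of network pairs
whose edge strengths covary with NAS, ten health/social-support measures
generated from three latent factors (one of which, HAR, moderates the
stress-connectivity coupling), and gestational age at delivery negatively
coupled to NAS.

Ground-truth columns (latent NAS, latent health factors, planted network
labels) are carried separately from the analysis-facing tables so that the
analysis stages never see them; tests compare estimates against them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

SCALE_COLUMNS = ["cesd", "stai_t", "pswq", "psst", "swls"]

HEALTH_COLUMNS = [
    "diet", "exercise", "ecr_anxiety",
    "fes_cohesion", "fes_expressiveness", "fes_conflict",
    "sleep", "medical_adherence", "substance_use", "ecr_avoidance",
]

# Loadings of the ten health/social-support measures on the three latent
# factors (Health Engagement, Family Systems, Health & Adult Relationship).
# Substance use and attachment avoidance load negatively on HAR; family
# conflict loads negatively on FS.
HEALTH_LOADINGS = np.array([
    # HE    FS    HAR
    [0.80, 0.00, 0.00],   # diet
    [0.75, 0.00, 0.00],   # exercise
    [0.60, 0.00, 0.00],   # ecr_anxiety
    [0.00, 0.80, 0.00],   # fes_cohesion
    [0.00, 0.70, 0.00],   # fes_expressiveness
    [0.00, -0.75, 0.00],  # fes_conflict
    [0.00, 0.00, 0.80],   # sleep
    [0.00, 0.00, 0.75],   # medical_adherence
    [0.00, 0.00, -0.70],  # substance_use
    [0.00, 0.00, -0.65],  # ecr_avoidance
])

HEALTH_FACTOR_NAMES = ["HE", "FS", "HAR"]

_GRID_SPACING_MM = 18.0
_CLOSE_PAIR_OFFSET = np.array([2.5, 2.5, 1.6])  # |offset| ~ 3.9 mm < 10 mm

_LOBES = ["frontal", "parietal", "temporal", "occipital", "subcortical", "cerebellar"]


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the cohort the pipeline is designed around: 118
    mother-fetus dyads scanned at 26-39 weeks gestation with an average of
    159 low-motion frames (SD 42) per subject, delivery at 39.4 +/- 1.1
    weeks, and five stress scales with loadings 0.8/0.8/0.7/0.7/0.6 on one
    latent factor (satisfaction-with-life keyed negatively).
    """

    n_subjects: int = 118
    n_roi: int = 60
    n_networks: int = 16
    frames_mean: int = 159
    frames_sd: int = 42
    frames_min: int = 20
    rho_within: float = 0.6
    rho_between: float = 0.05
    stress_coupled_pairs: tuple = (("N01", "N02"), ("N03", "N03"))
    coupling_slope: float = 0.02
    loading_vector: tuple = (0.8, 0.8, 0.7, 0.7, 0.6)
    har_moderation_slope: float = 0.3
    har_nas_r: float = -0.35
    delivery_beta: float = -0.396
    motion_rot_nas_r: float = 0.0
    n_close_pairs: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_roi < 2 or self.n_networks < 1 or self.n_networks > self.n_roi:
            raise ValueError("need 2 <= n_networks <= n_roi")
        if not (0 <= self.rho_between < self.rho_within < 1):
            raise ValueError("require 0 <= rho_between < rho_within < 1")
        if len(self.loading_vector) != 5 or not all(0 < l < 1 for l in self.loading_vector):
            raise ValueError("loading_vector must hold 5 values in (0, 1)")
        if self.frames_min < 10:
            raise ValueError("frames_min must be >= 10")
        if not -1 < self.har_nas_r < 1 or not -1 < self.motion_rot_nas_r < 1:
            raise ValueError("correlations must lie in (-1, 1)")
        if 2 * self.n_close_pairs > self.n_roi:
            raise ValueError("too many close pairs for n_roi")

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**{k: tuple(map(tuple, v)) if k == "stress_coupled_pairs" else
                     (tuple(v) if k == "loading_vector" else v)
                     for k, v in raw.items()})
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        raw["stress_coupled_pairs"] = [list(p) for p in self.stress_coupled_pairs]
        raw["loading_vector"] = list(self.loading_vector)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh)


@dataclass
class SyntheticCohort:
    """Generated cohort: analysis-facing tables plus withheld ground truth."""

    subjects: pd.DataFrame            # id, sex, ga_scan, ga_delivery, scales, health, motion, frames
    roi_meta: pd.DataFrame            # roi_id, hemisphere, lobe, x, y, z
    timeseries: dict                  # subject id -> (frames x n_roi) float array
    truth: pd.DataFrame | None = None       # id, latent_nas, HE, FS, HAR
    roi_truth: pd.DataFrame | None = None   # roi_id, true_network
    config: GeneratorConfig | None = None

    @property
    def has_truth(self) -> bool:
        return self.truth is not None


def network_labels(n_networks: int) -> list:
    return [f"N{i + 1:02d}" for i in range(n_networks)]


def _roi_networks(n_roi: int, n_networks: int) -> np.ndarray:
    """Contiguous, near-equal-sized planted network assignment."""
    sizes = np.full(n_networks, n_roi // n_networks)
    sizes[: n_roi % n_networks] += 1
    return np.repeat(np.arange(n_networks), sizes)


def _base_correlation(net: np.ndarray, rho_within: float, rho_between: float) -> np.ndarray:
    same = net[:, None] == net[None, :]
    c = np.where(same, rho_within, rho_between)
    np.fill_diagonal(c, 1.0)
    return c


def nearest_pd_correlation(c: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue-floored positive-definite repair, renormalised to unit diagonal."""
    c = (c + c.T) / 2.0
    vals, vecs = np.linalg.eigh(c)
    if vals.min() >= floor:
        return c
    vals = np.maximum(vals, floor)
    rep = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(rep))
    rep = rep / np.outer(d, d)
    np.fill_diagonal(rep, 1.0)
    if np.linalg.eigvalsh(rep).min() <= 0:
        raise ValueError("correlation matrix not positive definite after repair")
    return rep


def _roi_coordinates(n_roi: int, n_close_pairs: int, rng: np.random.Generator) -> np.ndarray:
    """ROI centres on a jittered 3-D grid; the first n_close_pairs consecutive
    pairs (0,1), (2,3), ... are planted < 10 mm apart, all other pairs are
    guaranteed > 10 mm apart."""
    side = int(np.ceil(n_roi ** (1 / 3)))
    grid = np.array([(i, j, k) for i in range(side) for j in range(side) for k in range(side)],
                    dtype=float)[:n_roi]
    coords = grid * _GRID_SPACING_MM
    coords -= coords.mean(axis=0)
    coords += rng.uniform(-1.0, 1.0, size=coords.shape)
    for p in range(n_close_pairs):
        coords[2 * p + 1] = coords[2 * p] + _CLOSE_PAIR_OFFSET
    return coords


def _make_roi_meta(cfg: GeneratorConfig, rng: np.random.Generator):
    net = _roi_networks(cfg.n_roi, cfg.n_networks)
    coords = _roi_coordinates(cfg.n_roi, cfg.n_close_pairs, rng)
    labels = network_labels(cfg.n_networks)
    lobe_band = np.digitize(coords[:, 2], np.quantile(coords[:, 2], np.linspace(0, 1, len(_LOBES) + 1)[1:-1]))
    meta = pd.DataFrame({
        "roi_id": [f"roi{j:03d}" for j in range(cfg.n_roi)],
        "hemisphere": np.where(coords[:, 0] < 0, "L", "R"),
        "lobe": [_LOBES[b] for b in lobe_band],
        "x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2],
    })
    roi_truth = pd.DataFrame({"roi_id": meta["roi_id"],
                              "true_network": [labels[g] for g in net]})
    return meta, roi_truth, net


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort (subject table, ROI metadata, timeseries).

    The per-subject ROI correlation matrix is the planted block matrix with
    edges in ``stress_coupled_pairs`` shifted by
    ``coupling_slope * NAS_i * (1 + har_moderation_slope * HAR_i)`` on the
    correlation scale, clipped and repaired to positive definite.
    Identical seeds give bit-identical cohorts.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects

    # --- latent structure -------------------------------------------------
    nas = rng.standard_normal(n)
    loadings = np.asarray(cfg.loading_vector)
    scale_noise = rng.standard_normal((n, 5))
    scales = loadings * nas[:, None] + np.sqrt(1 - loadings ** 2) * scale_noise
    scales[:, SCALE_COLUMNS.index("swls")] *= -1.0  # satisfaction keyed opposite to stress

    # three health/support factors; HAR correlated with NAS (higher stress,
    # lower health-and-relationship scores)
    he = rng.standard_normal(n)
    fs = rng.standard_normal(n)
    har = cfg.har_nas_r * nas + np.sqrt(1 - cfg.har_nas_r ** 2) * rng.standard_normal(n)
    factors = np.column_stack([he, fs, har])
    uniq = np.sqrt(1 - (HEALTH_LOADINGS ** 2).sum(axis=1))
    health = factors @ HEALTH_LOADINGS.T + uniq * rng.standard_normal((n, 10))

    # --- demographics, gestational ages, motion ---------------------------
    from scipy.stats import truncnorm
    a, b = (26.0 - 32.9) / 3.87, (39.0 - 32.9) / 3.87
    ga_scan = truncnorm.rvs(a, b, loc=32.9, scale=3.87, size=n, random_state=rng)
    ga_delivery = 39.4 + cfg.delivery_beta * nas + rng.normal(0.0, 1.1, n)
    ga_delivery = np.maximum(ga_delivery, ga_scan + 0.2)
    sex = rng.choice(["F", "M"], size=n)
    maternal_age = rng.normal(25.1, 4.5, n).clip(18, 45)
    income = np.exp(rng.normal(10.0, 0.6, n)).round(0).astype(int)
    motion_xyz = np.clip(0.2 + 0.1 * rng.standard_normal(n), 0.01, 0.52)
    r = cfg.motion_rot_nas_r
    motion_pyr = np.clip(0.85 + 0.12 * (r * nas + np.sqrt(1 - r ** 2) * rng.standard_normal(n)),
                         0.3, 1.5)
    frames = np.maximum(np.rint(rng.normal(cfg.frames_mean, cfg.frames_sd, n)).astype(int),
                        cfg.frames_min)
    if (frames < cfg.frames_min).any():
        raise ValueError("frame counts below frames_min")

    # --- ROI geometry and planted networks --------------------------------
    roi_meta, roi_truth, net = _make_roi_meta(cfg, rng)
    labels = network_labels(cfg.n_networks)
    pair_of_edge = np.zeros((cfg.n_roi, cfg.n_roi), dtype=bool)
    if cfg.coupling_slope != 0.0:
        coupled = {frozenset(p) for p in cfg.stress_coupled_pairs}
        for p in coupled:
            if not p <= set(labels):
                raise ValueError(f"stress_coupled_pairs references unknown network: {sorted(p)}")
        for i in range(cfg.n_roi):
            for j in range(cfg.n_roi):
                pair_of_edge[i, j] = frozenset((labels[net[i]], labels[net[j]])) in coupled
        np.fill_diagonal(pair_of_edge, False)

    base = _base_correlation(net, cfg.rho_within, cfg.rho_between)

    # --- per-subject timeseries -------------------------------------------
    ids = [f"sub{i + 1:03d}" for i in range(n)]
    timeseries = {}
    for i, sid in enumerate(ids):
        shift = cfg.coupling_slope * nas[i] * (1.0 + cfg.har_moderation_slope * har[i])
        c = base.copy()
        if shift != 0.0:
            c[pair_of_edge] = np.clip(c[pair_of_edge] + shift, -0.98, 0.98)
        c = nearest_pd_correlation(c)
        chol = np.linalg.cholesky(c)
        timeseries[sid] = rng.standard_normal((frames[i], cfg.n_roi)) @ chol.T

    subjects = pd.DataFrame({
        "id": ids, "sex": sex,
        "ga_scan": ga_scan, "ga_delivery": ga_delivery,
        **{col: scales[:, k] for k, col in enumerate(SCALE_COLUMNS)},
        **{col: health[:, k] for k, col in enumerate(HEALTH_COLUMNS)},
        "maternal_age": maternal_age, "income": income,
        "motion_xyz": motion_xyz, "motion_pyr": motion_pyr,
        "frame_count": frames,
    })
    truth = pd.DataFrame({"id": ids, "latent_nas": nas, "HE": he, "FS": fs, "HAR": har})
    return SyntheticCohort(subjects=subjects, roi_meta=roi_meta, timeseries=timeseries,
                           truth=truth, roi_truth=roi_truth, config=cfg)


# --- persistence ----------------------------------------------------------

_FLOAT_FMT = "%.17g"  # round-trip exact for float64


def write_cohort(cohort: SyntheticCohort, out_dir, timeseries_format: str = "npz") -> None:
    """Persist a cohort. Ground-truth columns go to separate truth files so
    the analysis-facing tables stay blind to them."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.subjects.to_csv(out / "cohort.csv", index=False, float_format=_FLOAT_FMT)
    cohort.roi_meta.to_csv(out / "roi.csv", index=False, float_format=_FLOAT_FMT)
    if cohort.truth is not None:
        cohort.truth.to_csv(out / "truth.csv", index=False, float_format=_FLOAT_FMT)
    if cohort.roi_truth is not None:
        cohort.roi_truth.to_csv(out / "roi_truth.csv", index=False)
    if timeseries_format == "npz":
        np.savez(out / "timeseries.npz", **cohort.timeseries)
    elif timeseries_format == "csv":
        ts_dir = out / "timeseries"
        ts_dir.mkdir(exist_ok=True)
        for sid, ts in cohort.timeseries.items():
            np.savetxt(ts_dir / f"{sid}.csv", ts, delimiter=",", fmt=_FLOAT_FMT)
    else:
        raise ValueError(f"unknown timeseries_format: {timeseries_format!r}")
    if cohort.config is not None:
        cohort.config.to_yaml(out / "generator.yaml")


def read_cohort(in_dir) -> SyntheticCohort:
    """Load a cohort written by :func:`write_cohort`. Truth files are
    optional; when absent the truth attributes are ``None``."""
    src = Path(in_dir)
    try:
        subjects = pd.read_csv(src / "cohort.csv")
        roi_meta = pd.read_csv(src / "roi.csv")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed cohort file under {src}: {exc}") from exc
    if len(subjects) == 0:
        raise ValueError("cohort has 0 subjects")
    truth = pd.read_csv(src / "truth.csv") if (src / "truth.csv").exists() else None
    roi_truth = pd.read_csv(src / "roi_truth.csv") if (src / "roi_truth.csv").exists() else None
    npz = src / "timeseries.npz"
    timeseries = {}
    if npz.exists():
        with np.load(npz) as archive:
            timeseries = {sid: archive[sid] for sid in archive.files}
    elif (src / "timeseries").is_dir():
        for f in sorted((src / "timeseries").glob("*.csv")):
            timeseries[f.stem] = np.loadtxt(f, delimiter=",", ndmin=2)
    config = None
    if (src / "generator.yaml").exists():
        config = GeneratorConfig.from_yaml(src / "generator.yaml")
    return SyntheticCohort(subjects=subjects, roi_meta=roi_meta, timeseries=timeseries,
                           truth=truth, roi_truth=roi_truth, config=config)
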