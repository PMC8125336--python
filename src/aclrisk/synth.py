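"""Two-tier synthetic-data generator.

Tier 1 (feature level) draws athlete x 13 feature tables from per-group
multivariate Gaussians calibrated to the published cohort statistics of
at-risk (R) and not-at-risk (NR) female basketball players, together with
LESS item records whose medians respect the group labels and whose severity
is rank-coupled to the athlete's jump-task ellipse area.

Tier 2 (signal level) manufactures raw IMU + optoelectronic trials whose
*extracted* features equal known ground truth, so the whole
orientation -> events -> features chain is testable without real recordings.
The signal model is additive and piecewise (stance / flight / landing or
hold / descent / ascent); it is an idealization, not a biomechanical
simulation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import _quat
from .events import LEDSeries
from .features import FEATURE_NAMES
from .less import LESSRecord
from .orientation import GRAVITY, IMUTrial

# ---------------------------------------------------------------------------
# Tier 1: feature-level cohorts

#: published group feature means/SDs, FEATURE_NAMES order
_R_MEAN = [0.21, 2.7, 1.5, 2.8, 1.5, 247.4, 169.4, 3.22, 0.8, 0.6, 0.4, 0.5, 16.8]
_R_SD = [0.04, 0.9, 0.5, 0.2, 0.2, 85.6, 26.7, 0.95, 0.1, 0.1, 0.1, 0.0, 2.7]
_NR_MEAN = [0.33, 2.9, 1.6, 1.1, 0.7, 95.6, 70.1, 3.90, 0.8, 0.6, 0.5, 0.7, 26.0]
_NR_SD = [0.06, 0.8, 0.3, 0.1, 0.2, 19.4, 14.9, 1.23, 0.3, 0.2, 0.2, 0.0, 5.3]

#: jump-task instability block with strong mutual redundancy
_REDUNDANT_BLOCK = ["mCMJ_PL_ML", "mCMJ_EA", "mCMJ_RMS_z", "mCMJ_RMS_xy"]


def default_correlation(
    block_r: float = 0.7, background_r: float = 0.2
) -> np.ndarray:
    """Default inter-feature correlation: r=0.7 within the jump instability
    block (PL_ML, EA, RMS_z, RMS_xy), r=0.2 elsewhere.

    The block reflects that the group-separating jump features co-vary
    strongly (they all measure the same landing instability), which is what
    makes permutation importance dilute across them.
    """
    p = len(FEATURE_NAMES)
    corr = np.full((p, p), background_r)
    idx = [FEATURE_NAMES.index(n) for n in _REDUNDANT_BLOCK]
    for i in idx:
        for j in idx:
            corr[i, j] = block_r
    np.fill_diagonal(corr, 1.0)
    return corr


@dataclass
class GroupFeatureModel:
    """Multivariate-Gaussian feature model of one risk group."""

    group_label: str  # "R" or "NR"
    mean: np.ndarray
    sd: np.ndarray
    corr: np.ndarray = field(default_factory=default_correlation)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.corr = np.asarray(self.corr, dtype=float)
        p = len(FEATURE_NAMES)
        if self.group_label not in ("R", "NR"):
            raise ValueError("group_label must be 'R' or 'NR'")
        if self.mean.shape != (p,) or self.sd.shape != (p,):
            raise ValueError(f"mean/sd must have {p} entries")
        if np.any(self.sd < 0):
            raise ValueError("sd entries must be nonnegative")
        if self.corr.shape != (p, p) or not np.allclose(self.corr, self.corr.T):
            raise ValueError("corr must be a symmetric 13x13 matrix")
        if not np.allclose(np.diag(self.corr), 1.0):
            raise ValueError("corr must have a unit diagonal")
        if np.linalg.eigvalsh(self.corr).min() < -1e-9:
            raise ValueError("corr must be positive semi-definite")

    def covariance(self) -> np.ndarray:
        return self.corr * np.outer(self.sd, self.sd)


def risk_group_model(corr: np.ndarray | None = None) -> GroupFeatureModel:
    return GroupFeatureModel(
        "R", _R_MEAN, _R_SD, default_correlation() if corr is None else corr
    )


def no_risk_group_model(corr: np.ndarray | None = None) -> GroupFeatureModel:
    return GroupFeatureModel(
        "NR", _NR_MEAN, _NR_SD, default_correlation() if corr is None else corr
    )


def default_group_models() -> dict[str, GroupFeatureModel]:
    return {"NR": no_risk_group_model(), "R": risk_group_model()}


@dataclass
class SyntheticCohort:
    """A sampled cohort: feature table, LESS records and labels per athlete."""

    features: pd.DataFrame  # athlete_id + 13 feature columns
    less_records: list[LESSRecord]
    labels: np.ndarray  # "R"/"NR" per athlete
    seed: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not (len(self.features) == len(self.less_records) == len(self.labels)):
            raise ValueError("features, LESS records and labels must align")
        for rec, lab in zip(self.less_records, self.labels):
            if rec.label != lab:
                raise ValueError(
                    f"LESS median of athlete {rec.athlete_id} contradicts label {lab}"
                )

    @property
    def feature_matrix(self) -> np.ndarray:
        return self.features[FEATURE_NAMES].to_numpy()

    def to_dir(self, out: str | Path) -> None:
        from .less import records_to_csv, records_to_json

        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        self.features.to_csv(out / "features.csv", index=False)
        (out / "labels.json").write_text(
            json.dumps(
                {
                    str(a): lab
                    for a, lab in zip(self.features["athlete_id"], self.labels)
                },
                indent=1,
            )
        )
        records_to_json(self.less_records, out / "less_records.json")
        records_to_csv(self.less_records, out / "less_items.csv")


def _sample_group_rows(
    n: int, model: GroupFeatureModel, rng: np.random.Generator
) -> np.ndarray:
    """Draw n nonnegative feature rows; rows with any negative entry are
    rejected and redrawn whole (no point mass at 0)."""
    p = len(FEATURE_NAMES)
    chol = np.linalg.cholesky(model.corr + 1e-10 * np.eye(p))
    rows = np.empty((n, p))
    filled = 0
    attempts = 0
    while filled < n:
        attempts += 1
        if attempts > 1000:
            raise RuntimeError("rejection sampling failed; model mass is negative")
        z = rng.standard_normal((n, p))
        cand = model.mean + (z @ chol.T) * model.sd
        good = cand[(cand >= 0).all(axis=1)]
        take = min(len(good), n - filled)
        rows[filled : filled + take] = good[:take]
        filled += take
    return rows


def sample_feature_cohort(
    n_nr: int,
    n_r: int,
    models: dict[str, GroupFeatureModel] | None = None,
    seed: int | None = None,
    less_target_means: tuple[float, float] = (3.5, 7.5),
    less_target_rho: float = 0.88,
) -> SyntheticCohort:
    """Sample a feature-level cohort of ``n_nr`` NR and ``n_r`` R athletes.

    Feature rows come from each group's truncated multivariate Gaussian;
    LESS records are generated with the requested group mean scores and
    EA-score rank coupling.
    """
    if n_nr < 1 or n_r < 1:
        raise ValueError("need at least one athlete per group")
    models = models or default_group_models()
    rng = np.random.default_rng(seed)
    rows_nr = _sample_group_rows(n_nr, models["NR"], rng)
    rows_r = _sample_group_rows(n_r, models["R"], rng)
    rows = np.vstack([rows_nr, rows_r])
    labels = np.array(["NR"] * n_nr + ["R"] * n_r)
    ids = [f"A{i:03d}" for i in range(1, n_nr + n_r + 1)]
    df = pd.DataFrame(rows, columns=FEATURE_NAMES)
    df.insert(0, "athlete_id", ids)
    ea = rows[:, FEATURE_NAMES.index("mCMJ_EA")]
    records = generate_less_records(
        labels,
        target_means=less_target_means,
        target_rho=less_target_rho,
        ea=ea,
        rng=rng,
        athlete_ids=ids,
    )
    return SyntheticCohort(df, records, labels, seed)


# -- LESS generation --------------------------------------------------------

_ITEM_CAPS = np.array([1] * 15 + [2, 2])


def _items_for_score(score: int, rng: np.random.Generator) -> np.ndarray:
    items = np.zeros(17, dtype=int)
    remaining = int(score)
    while remaining > 0:
        open_idx = np.flatnonzero(items < _ITEM_CAPS)
        items[rng.choice(open_idx)] += 1
        remaining -= 1
    return items


def _draw_medians(
    labels: np.ndarray, means: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Integer median targets per athlete: binomial within each group's
    admissible score range, matching the group mean."""
    mean_nr, mean_r = means
    out = np.empty(len(labels), dtype=int)
    is_nr = labels == "NR"
    if is_nr.any():
        if not 0 <= mean_nr <= 5:
            raise ValueError(
                f"NR target mean {mean_nr} unreachable: medians must be <= 5"
            )
        out[is_nr] = rng.binomial(5, mean_nr / 5.0, size=is_nr.sum())
    if (~is_nr).any():
        if not 6 <= mean_r <= 19:
            raise ValueError(
                f"R target mean {mean_r} unreachable: medians must be in 6..19"
            )
        out[~is_nr] = 6 + rng.binomial(13, (mean_r - 6) / 13.0, size=(~is_nr).sum())
    return out


def _assign_by_severity(
    medians: np.ndarray,
    labels: np.ndarray,
    severity: np.ndarray,
) -> np.ndarray:
    """Within each group, give the larger median to the higher severity."""
    out = np.empty_like(medians)
    for group in ("NR", "R"):
        idx = np.flatnonzero(labels == group)
        if idx.size == 0:
            continue
        order = idx[np.argsort(severity[idx], kind="stable")]
        out[order] = np.sort(medians[idx])
    return out


def _calibrate_sigma(
    ea: np.ndarray,
    labels: np.ndarray,
    means: tuple[float, float],
    target_rho: float,
    rng: np.random.Generator,
    reps: int = 10,
) -> float:
    """Bisection on the severity-noise scale so that the EA-median Spearman
    correlation approaches ``target_rho``. Unreachable targets clamp to the
    nearest achievable value."""
    s_ea = float(np.std(ea))
    if s_ea == 0:
        return 1.0

    def mean_rho(sigma: float) -> float:
        vals = []
        for _ in range(reps):
            med = _draw_medians(labels, means, rng)
            sev = ea + sigma * rng.standard_normal(len(ea))
            assigned = _assign_by_severity(med, labels, sev)
            if np.std(assigned) == 0:
                return 0.0
            vals.append(stats.spearmanr(ea, assigned).statistic)
        return float(np.mean(vals))

    lo, hi = 1e-3 * s_ea, 1e3 * s_ea
    rho_lo, rho_hi = mean_rho(lo), mean_rho(hi)
    if target_rho >= rho_lo:
        return lo
    if target_rho <= rho_hi:
        return hi
    for _ in range(18):
        mid = np.sqrt(lo * hi)
        if mean_rho(mid) >= target_rho:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def generate_less_records(
    labels,
    target_means: tuple[float, float] = (3.5, 7.5),
    target_rho: float = 0.0,
    seed: int | None = None,
    ea: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    athlete_ids=None,
) -> list[LESSRecord]:
    """Generate 3x17 LESS item matrices consistent with the given labels.

    Per-athlete integer median targets are binomial within the label's
    admissible range (NR <= 5 < R) with the requested group means; when
    ``ea`` is given and ``target_rho`` is nonzero, medians are allocated by a
    noisy EA severity ranking whose noise scale is calibrated internally so
    the cohort Spearman correlation between EA and median score approaches
    ``target_rho``. Jump-to-jump score jitter keeps the median exact; items
    are filled uniformly at random within their 0/1 (items 1-15) or 0/1/2
    (items 16-17) ranges.
    """
    labels = np.asarray(labels)
    rng = rng if rng is not None else np.random.default_rng(seed)
    if abs(target_rho) > 1:
        raise ValueError("|target_rho| must be <= 1")
    if target_rho != 0 and ea is None:
        raise ValueError("coupling to EA requires the ea array")

    medians = _draw_medians(labels, target_means, rng)
    if ea is not None and target_rho != 0 and np.std(medians) > 0:
        sev_base = np.sign(target_rho) * np.asarray(ea, dtype=float)
        cal_rng = np.random.default_rng(rng.integers(2**31))
        sigma = _calibrate_sigma(
            sev_base, labels, target_means, abs(target_rho), cal_rng
        )
        severity = sev_base + sigma * rng.standard_normal(len(labels))
        medians = _assign_by_severity(medians, labels, severity)
    else:
        medians = _assign_by_severity(
            medians, labels, rng.standard_normal(len(labels))
        )

    records = []
    ids = athlete_ids or [f"A{i:03d}" for i in range(1, len(labels) + 1)]
    for athlete, med in zip(ids, medians):
        d_up = rng.integers(0, min(2, med, 19 - med) + 1)
        d_down = rng.integers(0, min(2, med) + 1)
        scores = [int(med), int(med + d_up), int(med - d_down)]
        rng.shuffle(scores)
        items = np.stack([_items_for_score(s, rng) for s in scores])
        records.append(LESSRecord(items, athlete))
    return records


# ---------------------------------------------------------------------------
# Tier 2: signal-level trials

_MCMJ_TARGET_KEYS = ("Ts", "PL", "PL_AP", "PL_ML", "EA", "RMS_z", "RMS_xy")
_SLS_TARGET_KEYS = ("T_DP", "PL", "PL_AP", "PL_ML", "EA", "theta_ymax")


@dataclass
class SignalRecipe:
    """Ground-truth feature targets a synthesized trial must realize.

    All sway/load targets are on the time-normalized reporting scale (the
    same scale the features are reported on); the generator multiplies by
    the window duration internally. Requested path-length triples that
    violate the geometric feasibility bounds
    ``sqrt(PL_AP^2 + PL_ML^2) <= PL <= PL_AP + PL_ML`` are projected onto the
    feasible interval at construction; :attr:`target_features` holds the
    projected promise and :attr:`requested` the original numbers.
    """

    task: str  # "mCMJ" | "SLS"
    sample_rate: float = 100.0
    seed: int | None = None
    depth_cm: float = 1.0
    ellipse_level: float = 0.99
    # mCMJ targets
    ts: float | None = None
    rms_z: float | None = None
    rms_xy: float | None = None
    # SLS targets
    t_dp: float | None = None
    theta_ymax: float | None = None
    # shared sway targets (normalized scale)
    pl: float = 0.0
    pl_ap: float = 0.0
    pl_ml: float = 0.0
    ea: float = 0.0
    requested: dict = field(init=False)
    target_features: dict = field(init=False)
    realized_features: dict | None = field(init=False, default=None)

    def __post_init__(self) -> None:
        if self.task not in ("mCMJ", "SLS"):
            raise ValueError("task must be 'mCMJ' or 'SLS'")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.task == "mCMJ":
            if self.ts is None or self.ts <= 0:
                raise ValueError("mCMJ recipe needs Ts > 0")
            if (self.rms_z or 0) < 0 or (self.rms_xy or 0) < 0:
                raise ValueError("RMS targets must be nonnegative")
        else:
            if self.t_dp is None or self.t_dp <= 0:
                raise ValueError("SLS recipe needs T_DP > 0")
            if self.theta_ymax is None or self.theta_ymax < 0:
                raise ValueError("SLS recipe needs theta_ymax >= 0")
        if self.ea < 0:
            raise ValueError("EA target must be nonnegative")
        if min(self.pl, self.pl_ap, self.pl_ml) < 0:
            raise ValueError("path-length targets must be nonnegative")

        self.requested = self._as_dict(self.pl)
        self.pl = self._project_pl()
        self.target_features = self._as_dict(self.pl)

    def _as_dict(self, pl: float) -> dict:
        if self.task == "mCMJ":
            return {
                "mCMJ_Ts": self.ts,
                "mCMJ_PL": pl,
                "mCMJ_PL_AP": self.pl_ap,
                "mCMJ_PL_ML": self.pl_ml,
                "mCMJ_EA": self.ea,
                "mCMJ_RMS_z": self.rms_z or 0.0,
                "mCMJ_RMS_xy": self.rms_xy or 0.0,
            }
        return {
            "SLS_T_DP": self.t_dp,
            "SLS_PL": pl,
            "SLS_PL_AP": self.pl_ap,
            "SLS_PL_ML": self.pl_ml,
            "SLS_EA": self.ea,
            "SLS_theta_ymax": self.theta_ymax,
        }

    def _project_pl(self) -> float:
        lo = float(np.hypot(self.pl_ap, self.pl_ml))
        hi = self.pl_ap + self.pl_ml
        if lo <= self.pl <= hi:
            return self.pl
        if self.pl > 0 and (self.pl < lo / 5 or self.pl > hi * 5):
            raise ValueError(
                f"PL target {self.pl} infeasible: beyond 5x the feasible "
                f"interval [{lo:.3g}, {hi:.3g}] set by PL_AP/PL_ML"
            )
        margin = 1e-9 + 1e-6 * max(lo, 1e-12)
        return float(np.clip(self.pl, lo + margin, max(lo + margin, hi - margin)))

    @classmethod
    def from_features(
        cls, task: str, feats: dict, sample_rate: float = 100.0, seed=None
    ) -> "SignalRecipe":
        """Build a recipe from a 13-feature mapping (e.g., a cohort row)."""
        p = task if task == "mCMJ" else "SLS"
        kw = dict(
            pl=feats[f"{p}_PL"],
            pl_ap=feats[f"{p}_PL_AP"],
            pl_ml=feats[f"{p}_PL_ML"],
            ea=feats[f"{p}_EA"],
        )
        if task == "mCMJ":
            kw |= dict(
                ts=feats["mCMJ_Ts"],
                rms_z=feats["mCMJ_RMS_z"],
                rms_xy=feats["mCMJ_RMS_xy"],
            )
        else:
            kw |= dict(t_dp=feats["SLS_T_DP"], theta_ymax=feats["SLS_theta_ymax"])
        return cls(task=task, sample_rate=sample_rate, seed=seed, **kw)


# -- sway-path constructor --------------------------------------------------

def _triangle(phase: np.ndarray) -> np.ndarray:
    """Triangle wave, amplitude 1, period 1, total variation 4 per period."""
    return 2.0 * np.abs(2.0 * np.mod(phase, 1.0) - 1.0) - 1.0


def _alloc_counts(n: int, weights: np.ndarray) -> np.ndarray:
    """Integer slot counts per type, largest-remainder, >= 1 where weight > 0."""
    w = np.asarray(weights, dtype=float)
    w = np.where(w < 1e-12, 0.0, w)
    if w.sum() == 0:
        raise ValueError("no positive weights")
    raw = n * w / w.sum()
    counts = np.floor(raw).astype(int)
    counts[(w > 0) & (counts == 0)] = 1
    while counts.sum() > n:
        i = np.argmax(counts)
        counts[i] -= 1
    rem = n - counts.sum()
    if rem > 0:
        order = np.argsort(-(raw - counts))
        for i in order[:rem]:
            counts[i] += 1 if w[i] > 0 else 0
        counts[np.argmax(w)] += n - counts.sum()
    return counts


def _interleave_types(counts: np.ndarray) -> np.ndarray:
    """Spread slot types evenly over the window (deterministic)."""
    pieces = []
    for t, c in enumerate(counts):
        if c > 0:
            pieces.append(np.stack([(np.arange(c) + 0.5) / c + 1e-9 * t,
                                    np.full(c, t)], axis=1))
    merged = np.concatenate(pieces)
    return merged[np.argsort(merged[:, 0], kind="stable")][:, 1].astype(int)


def _make_sway_path(
    n_pts: int,
    length: float,
    lx: float,
    ly: float,
    area: float,
    level: float,
    envelope: np.ndarray | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Piecewise path of ``n_pts`` samples with prescribed total, per-axis
    path lengths and confidence-ellipse area.

    Arc length is allocated exactly by splitting the window into x-only,
    y-only and fixed-slope diagonal slots (the mixing fraction solves the
    Minkowski bound analytically); positions follow triangle waves whose
    amplitudes are fixed-point-iterated to the ellipse-area target.
    """
    n_seg = n_pts - 1
    xy = np.zeros((n_pts, 2))
    if length <= 1e-12 or (lx <= 1e-12 and ly <= 1e-12):
        return xy
    env = np.ones(n_seg) if envelope is None else np.asarray(envelope[:n_seg], float)
    env = np.maximum(env, 1e-3)

    q = float(np.hypot(lx, ly))
    denom = lx + ly - q
    alpha = 0.0 if denom < 1e-12 else float(np.clip((length - q) / denom, 0.0, 1.0))
    solo_x, solo_y = alpha * lx, alpha * ly
    diag_x, diag_y = (1 - alpha) * lx, (1 - alpha) * ly
    diag_len = float(np.hypot(diag_x, diag_y))

    counts = _alloc_counts(n_seg, np.array([solo_x, solo_y, diag_len]))
    types = _interleave_types(counts)
    # the aspect choice locks both axes to the same wiggle count, so a
    # quarter-period offset decorrelates them (triangle autocorrelation
    # vanishes at lag T/4)
    phi_x0 = rng.uniform(0, 1)
    phi_y0 = phi_x0 + 0.25

    if area <= 1e-12:
        # collinear: one diagonal direction, back-and-forth
        amp = length / 6.0
        d_phi = env / env.sum() * length / (4 * max(amp, 1e-12))
        phase = phi_x0 + np.concatenate([[0.0], np.cumsum(d_phi)])
        u = np.array([lx, ly]) / max(q, 1e-12)
        line = amp * _triangle(phase)
        xy = np.outer(line - line[0], u)
        return xy

    f_quant = stats.f.ppf(level, 2, max(n_pts - 2, 1))
    prod = area / (2.0 * np.pi * f_quant)  # target sx * sy
    aspect = max(lx, 1e-9) / max(ly, 1e-9)
    sx = np.sqrt(prod * aspect)
    sy = np.sqrt(prod / aspect)
    amp_x, amp_y = np.sqrt(3.0) * sx, np.sqrt(3.0) * sy

    x = y = None
    for it in range(6):
        d_phi_x = np.zeros(n_seg)
        d_phi_y = np.zeros(n_seg)
        m_x, m_y, m_d = (types == 0), (types == 1), (types == 2)
        if m_x.any() and solo_x > 0:
            w = env[m_x] / env[m_x].sum()
            d_phi_x[m_x] = w * solo_x / (4 * amp_x)
        if m_y.any() and solo_y > 0:
            w = env[m_y] / env[m_y].sum()
            d_phi_y[m_y] = w * solo_y / (4 * amp_y)
        if m_d.any() and diag_len > 0:
            w = env[m_d] / env[m_d].sum()
            d_phi_x[m_d] = w * diag_x / (4 * amp_x)
            d_phi_y[m_d] = w * diag_y / (4 * amp_y)
        phase_x = phi_x0 + np.concatenate([[0.0], np.cumsum(d_phi_x)])
        phase_y = phi_y0 + np.concatenate([[0.0], np.cumsum(d_phi_y)])
        x = amp_x * _triangle(phase_x)
        y = amp_y * _triangle(phase_y)
        if it < 3:  # marginal-spread correction
            amp_x *= np.clip(sx / max(np.std(x, ddof=1), 1e-12), 0.5, 2.0)
            amp_y *= np.clip(sy / max(np.std(y, ddof=1), 1e-12), 0.5, 2.0)
        else:  # joint ellipse-area correction
            cov = np.cov(np.stack([x, y]), ddof=1)
            ea_r = np.pi * 2 * f_quant * np.sqrt(max(np.linalg.det(cov), 1e-18))
            s = np.clip(np.sqrt(area / max(ea_r, 1e-18)), 0.7, 1.4)
            amp_x *= s
            amp_y *= s
    xy = np.stack([x - x[0], y - y[0]], axis=1)
    return xy


def measure_path(
    xy: np.ndarray, duration: float, level: float = 0.99
) -> dict[str, float]:
    """Normalized sway measures of a path (generator-side ground truth)."""
    d = np.diff(xy, axis=0)
    pl = float(np.hypot(d[:, 0], d[:, 1]).sum()) / duration
    pl_ml = float(np.abs(d[:, 0]).sum()) / duration
    pl_ap = float(np.abs(d[:, 1]).sum()) / duration
    cov = np.cov(xy.T, ddof=1)
    det = max(float(np.linalg.det(cov)), 0.0)
    ea = float(2 * np.pi * stats.f.ppf(level, 2, len(xy) - 2) * np.sqrt(det)) / duration
    return {"PL": pl, "PL_AP": pl_ap, "PL_ML": pl_ml, "EA": ea}


# -- angle/quaternion plumbing ----------------------------------------------

def _quats_from_path(xy: np.ndarray, depth_cm: float) -> np.ndarray:
    """Minimal-rotation quaternions whose S-axis projection traces ``xy``."""
    n = len(xy)
    quats = np.empty((n, 4))
    ez = np.array([0.0, 0.0, 1.0])
    for k in range(n):
        s = np.array([-xy[k, 0] / depth_cm, -xy[k, 1] / depth_cm, 1.0])
        quats[k] = _quat.from_two_vectors(ez, s / np.linalg.norm(s))
    return quats


def _gyro_from_quats(quats: np.ndarray, dt: float) -> np.ndarray:
    """Body-frame angular velocity (deg/s) consistent with the quaternion
    sequence under exponential-map integration."""
    n = len(quats)
    gyro = np.zeros((n, 3))
    for k in range(n - 1):
        dq = _quat.mul(_quat.conj(quats[k]), quats[k + 1])
        gyro[k] = np.degrees(_quat.log_map(dq) / dt)
    if n > 1:
        gyro[-1] = gyro[-2]
    return gyro


def _gravity_accel(quats: np.ndarray) -> np.ndarray:
    """Specific force (sensor frame) of a quiet sensor at each orientation."""
    n = len(quats)
    acc = np.empty((n, 3))
    gz = np.array([0.0, 0.0, GRAVITY])
    for k in range(n):
        acc[k] = _quat.to_matrix(quats[k]).T @ gz
    return acc


# -- trial synthesizers -----------------------------------------------------

def synthesize_static_trial(
    duration: float = 2.0,
    sample_rate: float = 100.0,
    seed: int | None = None,
    noise_deg: float = 0.005,
    accel_noise: float = 0.02,
) -> IMUTrial:
    """Quiet upright calibration trial (tiny orientation and accel noise)."""
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate)) + 1
    dt = 1.0 / sample_rate
    time = np.arange(n) * dt
    ang = np.radians(noise_deg) * rng.standard_normal((n, 2))
    xy = np.tan(ang)  # depth 1 cm
    quats = _quats_from_path(xy, 1.0)
    gyro = _gyro_from_quats(quats, dt)
    accel = _gravity_accel(quats) + accel_noise * rng.standard_normal((n, 3))
    return IMUTrial(time, accel, gyro, meta={"task": "static"})


def synthesize_jump_trial(recipe: SignalRecipe) -> tuple[IMUTrial, LEDSeries]:
    """One monopodalic countermovement-jump repetition plus its LED series.

    Phases: upright stance (LED on), flight (LED off, near-zero specific
    force), landing. The landing window carries (i) a decaying rotation about
    the sensor's long axis whose rectified rate has its first minimum exactly
    at contact + Ts, (ii) a sway-path tilt trace realizing the PL/EA targets,
    and (iii) alternating-sign acceleration bursts realizing the RMS targets
    exactly after gravity removal. Ground truth actually realized is stored
    in ``recipe.realized_features``.
    """
    if recipe.task != "mCMJ":
        raise ValueError("recipe.task must be 'mCMJ'")
    rng = np.random.default_rng(recipe.seed)
    fs = recipe.sample_rate
    dt = 1.0 / fs
    t_stance, t_flight, t_post = 1.0, 0.25, 0.8

    n_w = int(round(recipe.ts * fs)) + 1
    ts_grid = (n_w - 1) * dt
    idx_takeoff = int(round(t_stance * fs))
    idx_contact = int(round((t_stance + t_flight) * fs))
    t_contact = idx_contact * dt
    n_total = idx_contact + n_w + int(round(t_post * fs))
    time = np.arange(n_total) * dt
    tau = np.arange(n_w) * dt  # window-relative time

    # sway path over the landing window, arc-length envelope tapering to a
    # floor at Ts so the gyro-norm minimum stays put
    env = np.cos(np.pi * tau[:-1] / (2 * ts_grid)) + 0.15
    tgt = recipe.target_features
    lx = tgt["mCMJ_PL_ML"] * ts_grid
    ly = tgt["mCMJ_PL_AP"] * ts_grid
    area = tgt["mCMJ_EA"] * ts_grid
    # a PL target sitting at the Minkowski bound forces a collinear path; if
    # the ellipse-area target then falls short, grant the path extra arc
    # length (recorded in the realized targets) until the area is realizable
    l_total = tgt["mCMJ_PL"] * ts_grid
    l_cap = (lx + ly) * 0.999
    for _ in range(8):
        state = rng.bit_generator.state
        xy_win = _make_sway_path(
            n_w, l_total, lx, ly, area, recipe.ellipse_level, env, rng
        )
        if area <= 0 or measure_path(xy_win, ts_grid)["EA"] * ts_grid >= 0.9 * area:
            break
        if l_total >= l_cap:
            break
        rng.bit_generator.state = state
        l_total = min(l_total * 1.15, l_cap)
    tgt = recipe.target_features = dict(tgt, mCMJ_PL=l_total / ts_grid)

    xy = np.zeros((n_total, 2))
    xy[idx_contact : idx_contact + n_w] = xy_win
    # ease the tilt back to upright after the window
    n_ease = min(int(round(0.4 * fs)), n_total - idx_contact - n_w)
    if n_ease > 0:
        fade = 0.5 * (1 + np.cos(np.pi * np.arange(1, n_ease + 1) / n_ease))
        xy[idx_contact + n_w : idx_contact + n_w + n_ease] = (
            xy_win[-1][None, :] * fade[:, None]
        )

    quats_tilt = _quats_from_path(xy / recipe.depth_cm, 1.0)

    # rotation about the sensor's long axis: |omega_z| = A cos(pi tau / 2 Ts)
    # falls to zero exactly at contact + Ts and rises again afterwards
    sway_rate = np.linalg.norm(np.diff(xy[idx_contact:idx_contact + n_w], axis=0),
                               axis=1)
    max_rate_deg = np.degrees(np.max(sway_rate, initial=0.0) / dt)
    amp_z = float(np.clip(5.0 * max_rate_deg, 250.0, 1900.0))
    omega_z = np.zeros(n_total)
    tau_all = (np.arange(n_total) - idx_contact) * dt
    in_win = (tau_all >= 0) & (tau_all <= ts_grid)
    omega_z[in_win] = amp_z * np.cos(np.pi * tau_all[in_win] / (2 * ts_grid))
    after = tau_all > ts_grid
    omega_z[after] = (
        amp_z
        * np.cos(np.pi * tau_all[after] / (2 * ts_grid))
        * np.exp(-np.maximum(tau_all[after] - ts_grid - 0.05, 0.0) / 0.3)
    )
    # exclusive cumsum: the realized finite-difference gyro then equals the
    # profile at the left sample, putting the |omega| zero exactly on the
    # contact + Ts grid point
    psi = np.concatenate([[0.0], np.cumsum(np.radians(omega_z))[:-1]]) * dt
    quats = np.empty((n_total, 4))
    ez = np.array([0.0, 0.0, 1.0])
    for k in range(n_total):
        quats[k] = _quat.mul(quats_tilt[k], _quat.from_axis_angle(ez, psi[k]))

    gyro = _gyro_from_quats(quats, dt)
    gyro += 0.02 * rng.standard_normal(gyro.shape)

    accel = _gravity_accel(quats)
    accel += 0.02 * rng.standard_normal(accel.shape)
    accel[idx_takeoff:idx_contact] = 0.02 * rng.standard_normal(
        (idx_contact - idx_takeoff, 3)
    )

    # landing bursts: alternating-sign impacts concentrated on an early
    # active stretch whose amplitude stays >= ~30 m/s^2, so the
    # accelerometer-validity gate is off on every burst sample (inactive
    # samples carry pure gravity, whose direction is harmless); scaled so the
    # window RMS after gravity removal is exact
    rms_z_raw = (recipe.rms_z or 0.0) * ts_grid
    rms_xy_raw = (recipe.rms_xy or 0.0) * ts_grid
    d = np.zeros((n_w, 3))
    lead = max(rms_z_raw, rms_xy_raw)
    if lead > 0:
        m_act = int(np.clip(np.ceil(n_w * min(1.0, (lead / 30.0) ** 2)), 2, n_w))
        signs = np.where(np.arange(m_act) % 2 == 0, 1.0, -1.0)
        boost = np.sqrt(n_w / m_act)
        if rms_z_raw > 0:
            d[:m_act, 2] = signs * rms_z_raw * boost
        if rms_xy_raw > 0:
            ang = rng.uniform(0, 2 * np.pi, m_act)
            d[:m_act, 0] = signs * rms_xy_raw * boost * np.cos(ang)
            d[:m_act, 1] = -signs * rms_xy_raw * boost * np.sin(ang)
    accel[idx_contact : idx_contact + n_w] = d + np.array([0.0, 0.0, GRAVITY])

    on = np.ones(n_total, dtype=bool)
    on[idx_takeoff:idx_contact] = False

    realized = measure_path(xy_win, ts_grid, recipe.ellipse_level)
    recipe.realized_features = {
        "mCMJ_Ts": ts_grid,
        "mCMJ_PL": realized["PL"],
        "mCMJ_PL_AP": realized["PL_AP"],
        "mCMJ_PL_ML": realized["PL_ML"],
        "mCMJ_EA": realized["EA"],
        "mCMJ_RMS_z": rms_z_raw / ts_grid,
        "mCMJ_RMS_xy": rms_xy_raw / ts_grid,
    }
    trial = IMUTrial(
        time, accel, gyro,
        meta={"task": "mCMJ", "t_contact": t_contact, "ts": ts_grid},
    )
    return trial, LEDSeries(time, on)


def synthesize_squat_trial(recipe: SignalRecipe) -> IMUTrial:
    """One single-leg-squat repetition.

    The knee-flexion angle theta_y rises as a quarter-sine from the hold to
    ``theta_ymax`` over ``T_DP`` and comes back during the ascent. Sway
    wiggles are added on both tilt axes; the medio-lateral (theta_y) wiggle
    is capped by an envelope that keeps the theta_y argmax at the ramp peak,
    so the descent-phase sway targets are realized best-effort and the
    actually realized values are stored in ``recipe.realized_features``.
    """
    if recipe.task != "SLS":
        raise ValueError("recipe.task must be 'SLS'")
    rng = np.random.default_rng(recipe.seed)
    fs = recipe.sample_rate
    dt = 1.0 / fs
    t_hold = 2.0
    n_w = int(round(recipe.t_dp * fs)) + 1
    t_dp = (n_w - 1) * dt
    t_asc = min(1.5, 0.5 * t_dp + 0.3)
    idx_start = int(round(t_hold * fs))
    idx_peak = idx_start + n_w - 1
    n_asc = int(round(t_asc * fs))
    n_total = idx_peak + n_asc + int(round(0.5 * fs))
    time = np.arange(n_total) * dt
    tau = np.arange(n_w) * dt

    theta_max = float(recipe.theta_ymax)
    # mostly quarter-sine, plus a small linear part so the peak has a defined
    # slope and its argmax is robust to orientation noise
    ramp = theta_max * (
        0.97 * np.sin(np.pi * tau / (2 * t_dp)) + 0.03 * tau / t_dp
    )
    theta_y = np.zeros(n_total)
    theta_y[idx_start : idx_peak + 1] = ramp
    u = np.arange(1, n_asc + 1) * dt
    theta_y[idx_peak + 1 : idx_peak + 1 + n_asc] = theta_max * np.cos(
        np.pi * np.minimum(u / t_asc, 1.0) / 2
    )

    # raw sway targets over the descent window
    tgt = recipe.target_features
    lx = tgt["SLS_PL_ML"] * t_dp
    ly = tgt["SLS_PL_AP"] * t_dp
    area = tgt["SLS_EA"] * t_dp

    # ML wiggle (adds to theta_y): envelope-capped so the argmax stays at the
    # ramp peak
    interior = slice(1, n_w - 1)
    env_x = np.sin(np.pi * tau / t_dp) ** 2
    with np.errstate(divide="ignore"):
        cap = np.min(
            (theta_max - ramp[interior] - 0.5) / np.maximum(env_x[interior], 1e-6)
        )
    amp_x_deg = float(np.clip(cap, 0.0, 12.0))
    ramp_tv = recipe.depth_cm * np.tan(np.radians(theta_max))
    leftover_x = max(0.0, lx - ramp_tv)
    wig_x = np.zeros(n_w)
    if amp_x_deg > 0.1 and leftover_x > 0:
        amp_x_path = recipe.depth_cm * np.tan(np.radians(amp_x_deg))
        cycles = leftover_x / (4 * amp_x_path)
        phase = rng.uniform(0, 1) + cycles * tau / t_dp
        wig_x = amp_x_deg * env_x * _triangle(phase)

    # AP wiggle (theta_x): amplitude from the ellipse-area target, trapezoid
    # envelope; fixed-point iterate amplitude and cycle count
    f_quant = stats.f.ppf(recipe.ellipse_level, 2, max(n_w - 2, 1))
    env_y = np.clip(np.minimum(tau, t_dp - tau) / (0.1 * t_dp), 0.0, 1.0)
    theta_y_win = ramp + wig_x
    x_path = -recipe.depth_cm * np.tan(np.radians(theta_y_win))
    sx_real = max(float(np.std(x_path, ddof=1)), 1e-9)
    sy_target = area / (2 * np.pi * f_quant) / sx_real if area > 0 else 0.0
    amp_y_deg = float(
        np.clip(np.degrees(np.arctan(np.sqrt(3) * sy_target / recipe.depth_cm)),
                0.0, 20.0)
    )
    wig_y = np.zeros(n_w)
    if amp_y_deg > 0.05 and ly > 0:
        boost = 1.0  # compensates the arc length lost to the edge taper
        for _ in range(3):
            amp_y_path = recipe.depth_cm * np.tan(np.radians(amp_y_deg))
            cycles = max(boost * ly / (4 * max(amp_y_path, 1e-9)), 0.25)
            phase = rng.uniform(0, 1) + cycles * tau / t_dp
            wig_y = amp_y_deg * env_y * _triangle(phase)
            y_path = recipe.depth_cm * np.tan(np.radians(wig_y))
            ly_r = float(np.abs(np.diff(y_path)).sum())
            sy_r = max(float(np.std(y_path, ddof=1)), 1e-9)
            amp_y_deg = float(np.clip(amp_y_deg * sy_target / sy_r, 0.05, 20.0))
            if ly_r > 0:
                boost = float(np.clip(boost * ly / ly_r, 0.5, 4.0))
    theta_x = np.zeros(n_total)
    theta_x[idx_start : idx_peak + 1] = wig_y
    theta_y[idx_start : idx_peak + 1] = ramp + wig_x

    noise = 0.005
    theta_x += noise * rng.standard_normal(n_total)
    theta_y += noise * rng.standard_normal(n_total)

    # orientation, gyro and gravity-consistent accel from the angle series
    tx = np.radians(theta_x)
    ty = np.radians(theta_y)
    s_vec = np.stack(
        [np.sin(ty), -np.sin(tx) * np.cos(ty), np.cos(tx) * np.cos(ty)], axis=1
    )
    quats = np.empty((n_total, 4))
    ez = np.array([0.0, 0.0, 1.0])
    for k in range(n_total):
        quats[k] = _quat.from_two_vectors(ez, s_vec[k])
    gyro = _gyro_from_quats(quats, dt)
    accel = _gravity_accel(quats) + 0.02 * rng.standard_normal((n_total, 3))

    # realized ground truth on the nominal descent window
    sl = slice(idx_start, idx_peak + 1)
    path = -recipe.depth_cm * s_vec[sl, :2] / s_vec[sl, 2:3]
    realized = measure_path(path, t_dp, recipe.ellipse_level)
    recipe.realized_features = {
        "SLS_T_DP": t_dp,
        "SLS_PL": realized["PL"],
        "SLS_PL_AP": realized["PL_AP"],
        "SLS_PL_ML": realized["PL_ML"],
        "SLS_EA": realized["EA"],
        "SLS_theta_ymax": float(np.max(theta_y[sl])),
    }
    return IMUTrial(
        time, accel, gyro,
        meta={"task": "SLS", "t_start": idx_start * dt, "t_dp": t_dp},
    )
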