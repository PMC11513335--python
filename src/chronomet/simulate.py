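"""Synthetic challenge-study generator with known ground truth.

Emulates the structure of a two-block, multi-challenge metabolomics study:
kinetic response classes (washout decay, postprandial peaks, a fasting ramp,
circadian oscillation, flat), latent-module-induced partial-correlation
structure, per-subject response-amplitude variability, detection-limit
(left-censoring) and completely-at-random missingness, gross outliers, and
cross-platform duplicate measurements of the same metabolite.

The log2-scale signal for metabolite m, subject s at time t is

    baseline_m + scale_{s,m} * template_m(t) + rho_m * L_{module(m)}(s, t) + eps

with L a stationary unit-variance AR(1) latent process per (module, subject)
across the time-point grid and eps ~ Normal(0, noise_sd^2).  Abundances are
2**log2-signal; all outputs are deterministic functions of the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .schedules import build_schedule
from .study import MetaboliteInfo, ProfileDataset, StudyDesign

MEAL_CHALLENGES = ("SLDR", "SLD1", "SLD2", "OGTT", "OLTT")

TEMPLATE_KINDS = ("washout", "postprandial", "fasting_ramp", "circadian", "flat")


@dataclass(frozen=True)
class KineticTemplate:
    """One deterministic log2-scale response shape.

    kinds and parameters:

    - ``washout``: ``A * exp(-t_block / tau)`` — exposure acquired before the
      study decaying away; resets at each block start.
    - ``postprandial``: gamma-shaped impulse response summed over the meals
      preceding t in the same block; ``A`` is the peak amplitude (a float, or
      a mapping challenge name -> amplitude), ``a`` the shape, ``theta`` the
      time scale in minutes.
    - ``fasting_ramp``: saturating rise ``A * dt/(dt + h)`` during fasting
      (half-rise after ``h`` minutes), exponential decay with time constant
      ``tau`` after refeeding.
    - ``circadian``: ``A * sin(2*pi*clock/1440 + phi)``.
    - ``flat``: identically zero.
    """

    kind: str
    A: float | dict = 0.0
    tau: float = 1440.0
    a: float = 2.0
    theta: float = 45.0
    h: float = 720.0
    phi: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in TEMPLATE_KINDS:
            raise ConfigError(f"unknown template kind {self.kind!r}")
        for name in ("tau", "theta", "h"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"template parameter {name} must be > 0")

    # -- evaluation ------------------------------------------------------

    def value(self, block: int, clock_min: float, design: StudyDesign) -> float:
        if self.kind == "flat":
            return 0.0
        if self.kind == "washout":
            return float(self.A) * math.exp(-clock_min / self.tau)
        if self.kind == "circadian":
            return float(self.A) * math.sin(2 * math.pi * (clock_min % 1440.0) / 1440.0 + self.phi)
        if self.kind == "postprandial":
            total = 0.0
            peak = self.a**self.a * math.exp(-self.a)
            for ch in design.challenges:
                if ch.name not in MEAL_CHALLENGES:
                    continue
                if design.tp(ch.baseline_tp).block != block:
                    continue
                dt = clock_min - ch.onset_clock_min
                if dt <= 0:
                    continue
                if isinstance(self.A, dict):
                    amp = float(self.A.get(ch.name, 0.0))
                else:
                    amp = float(self.A)
                total += amp * (dt / self.theta) ** self.a * math.exp(-dt / self.theta) / peak
            return total
        # fasting_ramp
        try:
            fast = design.challenge("FASTING")
        except Exception:
            return 0.0
        if design.tp(fast.baseline_tp).block != block:
            return 0.0
        onset = fast.onset_clock_min
        try:
            refeed = design.challenge("SLDR").onset_clock_min
        except Exception:
            refeed = max(design.tp(t).clock_min for t in fast.tested_tps)
        amp = float(self.A)
        if clock_min <= refeed:
            dt = max(clock_min - onset, 0.0)
            return amp * dt / (dt + self.h)
        v_end = amp * (refeed - onset) / ((refeed - onset) + self.h)
        return v_end * math.exp(-(clock_min - refeed) / self.tau)


@dataclass(frozen=True)
class ModuleSpec:
    """A latent co-regulation module: its members share one AR(1) process."""

    id: str
    members: tuple[str, ...]
    loading: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.loading < 1.0:
            raise ConfigError(f"module {self.id}: loading must be in (0, 1)")


@dataclass
class SimConfig:
    """Parameters of one synthetic study.

    Defaults mirror the emulated study: 15 subjects on the built-in 56-time-
    point two-block schedule, log2-scale noise SD 0.5, AR(1) coefficient 0.6
    for the latent module processes, 5% detection-limit censoring and 1%
    additional completely-at-random missingness.
    """

    n_subjects: int = 15
    design: StudyDesign | None = None
    n_metabolites: int = 40
    modules: list[ModuleSpec] = field(default_factory=list)
    template_assignment: dict[str, KineticTemplate] = field(default_factory=dict)
    subject_variability: float = 0.2
    noise_sd: float = 0.5
    ar_coefficient: float = 0.6
    missing_mcar: float = 0.01
    missing_lod_quantile: float = 0.05
    outlier_rate: float = 0.0
    cross_platform_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    baseline_log2_range: tuple[float, float] = (6.0, 14.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design is None:
            self.design = build_schedule("humet56", subjects=list(range(1, self.n_subjects + 1)))
        for p, name in (
            (self.missing_mcar, "missing_mcar"),
            (self.outlier_rate, "outlier_rate"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.missing_lod_quantile < 1.0:
            raise ConfigError("missing_lod_quantile must be in [0, 1)")
        if not -1.0 < self.ar_coefficient < 1.0:
            raise ConfigError("ar_coefficient must be in (-1, 1)")
        seen: set[str] = set()
        for mod in self.modules:
            for m in mod.members:
                if m in seen:
                    raise ConfigError(f"metabolite {m!r} assigned to more than one module")
                seen.add(m)

    def uid(self, i: int) -> str:
        return f"met{i:03d}.P.nt-ms"


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline is asked to recover."""

    true_edges: set[frozenset]
    true_responders: dict[str, set[str]]
    template_assignment: dict[str, KineticTemplate]
    modules: list[ModuleSpec]
    injected_outliers: list[tuple[int, int, str]] = field(default_factory=list)


def default_catalog(cfg: SimConfig) -> list[MetaboliteInfo]:
    catalog = [
        MetaboliteInfo(
            uid=cfg.uid(i),
            display_name=f"met{i:03d}",
            fluid="P",
            platform="nt-ms",
            super_pathway="Xenobiotics",
        )
        for i in range(1, cfg.n_metabolites + 1)
    ]
    for uid_a, uid_b, _r in cfg.cross_platform_pairs:
        base = next(m for m in catalog if m.uid == uid_a)
        catalog.append(
            MetaboliteInfo(
                uid=uid_b,
                display_name=base.display_name,
                fluid=base.fluid,
                platform="t-ms",
                super_pathway=base.super_pathway,
            )
        )
    return catalog


def simulate_dataset(cfg: SimConfig) -> tuple[ProfileDataset, GroundTruth]:
    """Simulate one raw-scale dataset plus its ground truth."""
    design = cfg.design
    rng = np.random.default_rng(cfg.seed)
    uids = [cfg.uid(i) for i in range(1, cfg.n_metabolites + 1)]
    known = set(uids)
    for mod in cfg.modules:
        missing = [m for m in mod.members if m not in known]
        if missing:
            raise ConfigError(f"module {mod.id}: unknown member(s) {missing}")
    for uid in cfg.template_assignment:
        if uid not in known:
            raise ConfigError(f"template assigned to unknown metabolite {uid!r}")

    tps = design.tp_indices
    n_tp, n_sub, n_met = len(tps), len(design.subjects), len(uids)
    blocks = np.array([design.tp(t).block for t in tps])
    clocks = np.array([design.tp(t).clock_min for t in tps])

    # deterministic template matrix (n_tp, n_met)
    flat = KineticTemplate("flat")
    templates = [cfg.template_assignment.get(u, flat) for u in uids]
    temp = np.zeros((n_tp, n_met))
    for j, tpl in enumerate(templates):
        if tpl.kind == "flat":
            continue
        temp[:, j] = [tpl.value(int(b), float(c), design) for b, c in zip(blocks, clocks)]

    baselines = rng.uniform(*cfg.baseline_log2_range, size=n_met)
    scales = 1.0 + cfg.subject_variability * rng.standard_normal((n_sub, n_met))

    module_of = np.full(n_met, -1)
    loading = np.zeros(n_met)
    for k, mod in enumerate(cfg.modules):
        for m in mod.members:
            j = uids.index(m)
            module_of[j] = k
            loading[j] = mod.loading

    # stationary unit-variance AR(1) latents, one per (module, subject)
    phi = cfg.ar_coefficient
    latents = np.zeros((len(cfg.modules), n_sub, n_tp))
    for k in range(len(cfg.modules)):
        for s in range(n_sub):
            e = rng.standard_normal(n_tp)
            x = np.empty(n_tp)
            x[0] = e[0]
            innov = math.sqrt(1.0 - phi * phi)
            for t in range(1, n_tp):
                x[t] = phi * x[t - 1] + innov * e[t]
            latents[k, s] = x

    noise = cfg.noise_sd * rng.standard_normal((n_sub, n_tp, n_met))

    log2 = np.empty((n_sub, n_tp, n_met))
    for s in range(n_sub):
        log2[s] = baselines + scales[s] * temp
        for j in range(n_met):
            if module_of[j] >= 0:
                log2[s, :, j] += loading[j] * latents[module_of[j], s]
    log2 += noise

    all_uids = list(uids)
    planes = [log2]
    # cross-platform twins: same metabolite on a second platform, noise
    # calibrated so the expected log2-scale Pearson correlation equals r
    for uid_a, uid_b, r in cfg.cross_platform_pairs:
        if uid_a not in known:
            raise ConfigError(f"cross-platform pair references unknown uid {uid_a!r}")
        if not 0.0 < r <= 1.0:
            raise ConfigError("cross-platform attenuation must be in (0, 1]")
        j = uids.index(uid_a)
        x = log2[:, :, j]
        v = float(np.var(x))
        se = math.sqrt(max(v * (1.0 / (r * r) - 1.0), 0.0))
        twin = x + se * rng.standard_normal(x.shape)
        planes.append(twin[:, :, None])
        all_uids.append(uid_b)
    full = np.concatenate(planes, axis=2)

    abund = np.power(2.0, full)

    # left-censoring at the per-metabolite detection-limit quantile, then MCAR
    observed = np.ones_like(abund, dtype=bool)
    if cfg.missing_lod_quantile > 0:
        lod = np.quantile(abund.reshape(-1, abund.shape[2]), cfg.missing_lod_quantile, axis=0)
        observed &= abund >= lod
    if cfg.missing_mcar > 0:
        observed &= rng.random(abund.shape) >= cfg.missing_mcar

    # restrict to time points where the metabolite's fluid is sampled
    catalog = default_catalog(cfg)
    fluid_ok = np.ones((n_tp, len(all_uids)), dtype=bool)
    for j, uid in enumerate(all_uids):
        fluid = next(m.fluid for m in catalog if m.uid == uid)
        fluid_ok[:, j] = [fluid in design.tp(t).fluids_sampled for t in tps]
    observed &= fluid_ok[None, :, :]

    data = np.where(observed, abund, np.nan)
    idx = pd.MultiIndex.from_product([design.subjects, tps], names=["subject", "tp"])
    values = pd.DataFrame(
        data.reshape(n_sub * n_tp, len(all_uids)), index=idx, columns=all_uids
    )
    ds = ProfileDataset(catalog, design, values, "raw")

    true_edges = {
        frozenset({a, b})
        for mod in cfg.modules
        for i, a in enumerate(mod.members)
        for b in mod.members[i + 1 :]
    }
    responders: dict[str, set[str]] = {}
    for ch in design.challenges:
        base_row = tps.index(ch.baseline_tp)
        rows = [tps.index(t) for t in ch.tested_tps]
        hit = {
            uids[j]
            for j in range(n_met)
            if np.max(np.abs(temp[rows, j] - temp[base_row, j])) > 1e-9
        }
        responders[ch.name] = hit
    truth = GroundTruth(true_edges, responders, dict(cfg.template_assignment), list(cfg.modules))

    if cfg.outlier_rate > 0:
        ds, injected = inject_outliers(ds, cfg.outlier_rate, 6.0, cfg.seed + 1)
        truth.injected_outliers = injected
    return ds, truth


def inject_outliers(
    ds: ProfileDataset,
    rate: float,
    magnitude_sd_multiples: float = 6.0,
    seed: int = 0,
) -> tuple[ProfileDataset, list[tuple[int, int, str]]]:
    """Shift randomly chosen observed entries by a gross log2-scale amount.

    The shift is ``magnitude_sd_multiples`` times the per-(metabolite, time
    point) cross-subject SD of the log2 values (entries in groups with fewer
    than 3 observations or zero SD are not eligible).  At most one entry per
    (metabolite, time point) group is contaminated so each injected point
    stays a lone outlier within its group.  Returns the modified dataset and
    the injected (subject, tp, uid) list.
    """
    if not 0.0 <= rate <= 1.0:
        raise ConfigError("outlier rate must be in [0, 1]")
    if rate == 0.0:
        return ds, []
    rng = np.random.default_rng(seed)
    log2 = ds.transform_tag == "log2"
    vals = ds.values.copy()
    work = vals if log2 else np.log2(vals)
    sd = work.groupby(level="tp").std(ddof=1)
    count = work.groupby(level="tp").count()
    # shift "at least" the requested multiple: the per-(uid, tp) SD estimate is
    # noisy at small n, so take the larger of it and the metabolite's pooled
    # (rms over time points) SD
    pooled = np.sqrt((sd**2).mean(axis=0))
    injected: list[tuple[int, int, str]] = []
    subjects = list(ds.design.subjects)
    for uid in ds.uids:
        for tp in ds.design.tp_indices:
            if count.at[tp, uid] < 3 or not sd.at[tp, uid] > 0:
                continue
            observed = [s for s in subjects if pd.notna(vals.at[(s, tp), uid])]
            # per-entry rate, collapsed to at most one hit per group
            if rng.random() >= min(rate * len(observed), 1.0):
                continue
            subj = observed[rng.integers(len(observed))]
            x = vals.at[(subj, tp), uid] if log2 else math.log2(vals.at[(subj, tp), uid])
            group = vals.loc[[(s, tp) for s in observed], uid]
            mean = float(group.mean() if log2 else np.log2(group).mean())
            # shift away from the group mean so the contaminated point deviates
            # by at least the requested multiple by construction
            sign = 1.0 if x >= mean else -1.0
            shift = sign * magnitude_sd_multiples * max(sd.at[tp, uid], pooled[uid])
            if log2:
                vals.at[(subj, tp), uid] += shift
            else:
                vals.at[(subj, tp), uid] *= 2.0**shift
            injected.append((subj, tp, uid))
    return ds.with_values(vals), injected
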