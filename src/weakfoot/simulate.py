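"""Synthetic bilateral plantar-pressure gait with known ground truth.

Each subject walks with alternating left/right foot contacts.  A stance
emits half-sine pressure bursts that progress heel to toe (the rollover),
so the COP travels posterior to anterior within every step.  The high-risk
gait is modelled as *anterior rollover attenuation*: while in the high-risk
state, the weak foot's anterior sensors fire earlier and weaker, which
directly shrinks the anterior-posterior COP excursion (Std_y) that the
weak-foot selection rule keys on.

Phenotypes:

* ``DWF_LR`` — never in the high-risk state (low fall risk),
* ``DWF_HR`` — always in the high-risk state (persistent weak foot),
* ``RWF``   — the state toggles between steps via a symmetric two-state
  Markov chain, giving temporally clustered high-risk episodes; labelled
  high risk.

The Markov switching (rather than i.i.d. mixing) is what makes short-window
feature vectors disperse while long windows average out, i.e. what elevates
the DDI for RWF subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import Recording, SensorLayout, StepEvent, ValidationError

PHENOTYPES = ("DWF_LR", "DWF_HR", "RWF")

#: Per-row activation template (onset fraction, duration fraction, amplitude),
#: heel -> toe.  The rows jointly cover the whole stance interval.
DEFAULT_TEMPLATE = (
    (0.00, 0.55, 1.00),
    (0.15, 0.55, 1.05),
    (0.32, 0.53, 1.00),
    (0.50, 0.50, 0.85),
)

#: "Tired push-off" morph axis, heel -> toe: at morph phase phi the row
#: onsets are delayed by phi * _MORPH_ONSET and the amplitudes scaled by
#: (1 + phi * _MORPH_AMP).  Dwell time redistributes linearly with phi, so
#: COP dispersion features respond smoothly along the whole axis.
_MORPH_ONSET = (0.0, 0.08, 0.16, 0.24)
_MORPH_AMP = (0.0, -0.10, -0.20, -0.30)


def default_layout() -> dict[str, SensorLayout]:
    """Stylised 16-sensor insole: 4 columns x 4 rows (mm), heel at low y."""
    xs = (-15.0, -5.0, 5.0, 15.0)
    ys = (30.0, 90.0, 150.0, 210.0)
    coords = tuple((x, y) for y in ys for x in xs)
    return {side: SensorLayout(side, coords) for side in ("left", "right")}


@dataclass(frozen=True)
class GaitSimConfig:
    """Simulation knobs; the defaults emulate a two-minute corridor walk."""

    n_sensors: int = 16
    rate: float = 100.0          # Hz
    cadence: float = 110.0       # steps/min (both feet)
    duty: float = 1.1            # stance duration as a multiple of the step period
    step_cv: float = 0.03        # per-step timing jitter CV
    template: tuple[tuple[float, float, float], ...] = DEFAULT_TEMPLATE
    weak_side: str = "left"
    attenuation: float = 0.5     # anterior rollover attenuation in (0, 1]
    phenotype: str = "DWF_HR"
    switch_prob: float = 0.1     # per-step exit rate of the high-risk state (RWF)
    rwf_high_frac: float = 0.35  # stationary high-risk occupancy (RWF only)
    noise_add: float = 0.01      # additive in-burst sensor noise SD
    noise_mult: float = 0.08     # per-step amplitude noise CV
    shape_sigma: float = 0.02    # iid per-step rollover jitter (amp CV + onset SD)
    signature_sigma: float = 0.28  # per-subject fixed gait-signature spread
    fatigue: float = 0.55        # push-off morph phase reached by walk end
    drift_sigma: float = 0.01    # SD of the slow AR(1) rollover drift
    drift_rho: float = 0.90      # per-step autocorrelation of the drift
    total_steps: int = 222
    lead_in_s: float = 0.3

    def __post_init__(self):
        if self.phenotype not in PHENOTYPES:
            raise ValidationError(f"phenotype must be one of {PHENOTYPES}")
        if not (0.0 < self.attenuation <= 1.0):
            raise ValidationError("attenuation must lie in (0, 1]")
        if not (0.0 <= self.switch_prob <= 1.0):
            raise ValidationError("switch_prob must lie in [0, 1]")
        if not (0.0 < self.rwf_high_frac < 1.0):
            raise ValidationError("rwf_high_frac must lie in (0, 1)")
        if self.weak_side not in ("left", "right"):
            raise ValidationError("weak_side must be left or right")
        if self.total_steps < 4:
            raise ValidationError("need at least 4 steps")
        if self.n_sensors % len(self.template):
            raise ValidationError("n_sensors must be a multiple of the template rows")

    @property
    def risk_label(self) -> str:
        return "LR" if self.phenotype == "DWF_LR" else "HR"


@dataclass
class GroundTruth:
    """Programmed truth emitted alongside a synthetic recording."""

    contacts: list[StepEvent]
    weak_side: str
    states: np.ndarray          # per-step high-risk state (bool)
    phenotype: str
    risk_label: str
    meta: dict = field(default_factory=dict)


def _state_sequence(cfg: GaitSimConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.total_steps
    if cfg.phenotype == "DWF_LR":
        return np.zeros(n, dtype=bool)
    if cfg.phenotype == "DWF_HR":
        return np.ones(n, dtype=bool)
    # two-state Markov chain: exit rate switch_prob from the high-risk
    # state, entry rate scaled so the stationary occupancy is rwf_high_frac
    # (episodes of high-risk gait cover that fraction of the walk)
    pi = cfg.rwf_high_frac
    p_exit = cfg.switch_prob
    p_enter = min(p_exit * pi / max(1.0 - pi, 1e-9), 1.0)
    states = np.empty(n, dtype=bool)
    states[0] = rng.random() < pi
    u = rng.random(n - 1)
    for i in range(1, n):
        p = p_exit if states[i - 1] else p_enter
        states[i] = states[i - 1] ^ (u[i - 1] < p)
    return states


def simulate_subject(cfg: GaitSimConfig, seed: int | np.random.Generator = 0,
                     subject_id: str = "sim", layout: dict[str, SensorLayout] | None = None,
                     ) -> tuple[Recording, GroundTruth]:
    """Emit one synthetic bilateral recording plus its ground truth."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if layout is None:
        layout = default_layout()
    if layout["left"].n != cfg.n_sensors:
        raise ValidationError("layout sensor count disagrees with config")
    n_rows = len(cfg.template)
    per_row = cfg.n_sensors // n_rows
    row_of = np.repeat(np.arange(n_rows), per_row)
    # anteriority weight in [0, 1] per row, used to grade the attenuation
    y = np.asarray([c[1] for c in layout["left"].coords])
    row_y = np.array([y[row_of == r].mean() for r in range(n_rows)])
    anterior = (row_y - row_y.min()) / (row_y.max() - row_y.min())

    period = 60.0 / cfg.cadence
    onsets_s = np.empty(cfg.total_steps)
    durs_s = np.empty(cfg.total_steps)
    t = cfg.lead_in_s
    for i in range(cfg.total_steps):
        onsets_s[i] = t
        durs_s[i] = cfg.duty * period * max(1.0 + cfg.step_cv * rng.standard_normal(), 0.5)
        t += period * max(1.0 + cfg.step_cv * rng.standard_normal(), 0.5)
    total_dur = onsets_s[-1] + durs_s[-1] + cfg.lead_in_s
    n_frames = int(np.ceil(total_dur * cfg.rate))

    states = _state_sequence(cfg, rng)
    # per-subject gait signature, fixed for the whole walk: every cohort has
    # stable idiosyncratic pressure patterns, which give each feature real
    # between-subject spread (not just the programmed risk effect)
    sig_amp = {s: np.maximum(1.0 + cfg.signature_sigma * rng.standard_normal(cfg.n_sensors), 0.2)
               for s in ("left", "right")}
    sig_onset = {s: 0.3 * cfg.signature_sigma * rng.standard_normal(n_rows)
                 for s in ("left", "right")}
    # deterministic fatigue: the anterior push-off weakens monotonically over
    # the walk.  The slope varies between subjects but cancels in dispersion
    # ratios, so it anchors every subject's short/long window comparison.
    slope = cfg.fatigue * (0.8 + 0.4 * rng.random())
    progress = np.arange(cfg.total_steps) / max(cfg.total_steps - 1, 1)
    # slow shared rollover wander on top of the trend
    drift = np.empty(cfg.total_steps)
    drift[0] = rng.standard_normal()
    innov = rng.standard_normal(cfg.total_steps - 1)
    for i in range(1, cfg.total_steps):
        drift[i] = cfg.drift_rho * drift[i - 1] + \
            np.sqrt(1.0 - cfg.drift_rho ** 2) * innov[i - 1]
    sides = np.array(["left", "right"])[np.arange(cfg.total_steps) % 2]
    mats = {s: np.zeros((n_frames, cfg.n_sensors)) for s in ("left", "right")}
    contacts: list[StepEvent] = []

    for i in range(cfg.total_steps):
        side = str(sides[i])
        t0, D = onsets_s[i], durs_s[i]
        attenuated = states[i] and side == cfg.weak_side
        step_amp = max(1.0 + cfg.noise_mult * rng.standard_normal(), 0.1)
        # step-to-step motor variability: each row's amplitude and burst
        # onset jitter independently, perturbing every step's COP path
        row_jit = np.maximum(1.0 + cfg.shape_sigma * rng.standard_normal(n_rows), 0.05)
        onset_jit = 0.5 * cfg.shape_sigma * rng.standard_normal(n_rows)
        phi = slope * progress[i] + cfg.drift_sigma * drift[i]
        # per-row burst intervals (fractions of stance)
        o_eff = np.empty(n_rows)
        e_eff = np.empty(n_rows)
        for r in range(n_rows):
            o, d, _ = cfg.template[r]
            o = o + sig_onset[side][r] + onset_jit[r] + phi * _MORPH_ONSET[r]
            if attenuated:
                o = o * (1.0 - (1.0 - cfg.attenuation) * anterior[r])
            o = min(max(o, 0.0), 0.9)
            o_eff[r], e_eff[r] = o, min(o + d, 1.0)
        mat = mats[side]
        for s in range(cfg.n_sensors):
            r = row_of[s]
            amp = cfg.template[r][2] * sig_amp[side][s] * row_jit[r]
            amp = amp * max(1.0 + phi * _MORPH_AMP[r], 0.05)
            if attenuated:
                amp = amp * (1.0 - (1.0 - cfg.attenuation) * anterior[r])
            f0 = int(round((t0 + o_eff[r] * D) * cfg.rate))
            f1 = int(round((t0 + e_eff[r] * D) * cfg.rate))
            if f1 <= f0:
                continue
            phase = (np.arange(f0, f1) - f0 + 0.5) / (f1 - f0)
            burst = amp * step_amp * (0.1 + 0.9 * np.sin(np.pi * phase))
            if cfg.noise_add > 0:
                burst = burst + cfg.noise_add * rng.standard_normal(burst.size)
            mat[f0:f1, s] += np.maximum(burst, 0.0)
        # faint full-sole contact pedestal: keeps total force positive over
        # the whole stance (its COP sits at the sole centroid, so frames
        # dominated by real bursts are barely moved)
        g0 = int(round(t0 * cfg.rate))
        g1 = int(round((t0 + D) * cfg.rate))
        mat[g0:g1, :] += 0.04 * step_amp
        contacts.append(StepEvent(onset=int(round(t0 * cfg.rate)),
                                  end=int(round((t0 + D) * cfg.rate)), side=side))

    rec = Recording(
        subject_id=subject_id,
        label=cfg.risk_label,
        rate=cfg.rate,
        left=mats["left"],
        right=mats["right"],
        layout=layout,
        meta={"phenotype": cfg.phenotype, "weak_side": cfg.weak_side},
    )
    truth = GroundTruth(contacts=contacts, weak_side=cfg.weak_side, states=states,
                        phenotype=cfg.phenotype, risk_label=cfg.risk_label)
    return rec, truth


def simulate_cohort(n_per_cell: dict[str, int], cfg: GaitSimConfig | None = None,
                    seed: int = 0) -> tuple[list[Recording], list[GroundTruth]]:
    """Independent subjects per phenotype cell with per-subject derived seeds.

    ``n_per_cell`` maps phenotype -> count, e.g. ``{"DWF_LR": 16,
    "DWF_HR": 16, "RWF": 8}``.  Weak sides alternate across subjects.
    """
    if cfg is None:
        cfg = GaitSimConfig()
    unknown = set(n_per_cell) - set(PHENOTYPES)
    if unknown:
        raise ValidationError(f"unknown phenotypes: {sorted(unknown)}")
    ss = np.random.SeedSequence(seed)
    cells = [(ph, n_per_cell.get(ph, 0)) for ph in PHENOTYPES]
    total = sum(n for _, n in cells)
    children = ss.spawn(total)
    recs: list[Recording] = []
    truths: list[GroundTruth] = []
    k = 0
    for phenotype, count in cells:
        for j in range(count):
            sub_cfg = replace(cfg, phenotype=phenotype,
                              weak_side="left" if k % 2 == 0 else "right")
            rng = np.random.default_rng(children[k])
            rec, truth = simulate_subject(sub_cfg, rng,
                                          subject_id=f"sub{k:03d}_{phenotype}")
            recs.append(rec)
            truths.append(truth)
            k += 1
    return recs, truths
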