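"""Synthetic forensic cohorts and gel-lane traces.

The calibration study's per-case data are not public, so this module
generates cohorts with the same reported structure: 40 cases spanning
4.0–92.8 hours postmortem, ambient temperatures from a truncated normal on
[-7, 21] °C, 28/40 cases moved to 4 °C mortuary cooling, ages 2–90 years,
BMI 10.7–50.4, 23 female : 17 male.  Marker presence is drawn from logistic
functions of the case's true accumulated degree-days, using curves
reconstructed through the published (P50, P95) threshold pairs; the desmin
degradation chain is drawn sequentially so nesting (dp2 never without dp1,
dp3 never without dp1 and dp2) holds by construction.

Every stage of the pipeline can thus be exercised end-to-end and checked
against known ground truth: generated cohorts carry ``true_add`` and
``true_presence``, and :func:`generate_lane_traces` renders each case's
marker vector as synthetic densitometric traces (Gaussian bands on a noisy,
drifting baseline) for the band-calling stage.

All randomness flows from the seed recorded in the configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import LogisticCurve
from .densitometry import LadderCalibration, LaneTrace
from .panel import Panel, default_panel
from .thermal import TemperatureProfile, compute_add

__all__ = [
    "TruncNormal",
    "MarkerSpec",
    "GeneratorConfig",
    "TraceConfig",
    "SyntheticCase",
    "DEFAULT_MARKERS",
    "generate_cohort",
    "generate_lane_traces",
    "cohort_frame",
    "cohort_to_files",
    "read_cohort",
    "standard_ladder",
]


@dataclass(frozen=True)
class TruncNormal:
    """Normal(mean, sd) truncated to [lo, hi]."""

    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self):
        if not (self.lo < self.hi) or self.sd <= 0:
            raise ValueError(f"invalid truncated normal {self}")

    def sample(self, rng: np.random.Generator, size: int | None = None):
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return stats.truncnorm.rvs(
            a, b, loc=self.mean, scale=self.sd, size=size, random_state=rng
        )


@dataclass(frozen=True)
class MarkerSpec:
    """Generating curve of one degradation product.

    ``parent`` names the immediately earlier product of a nesting chain:
    the product is drawn only when its parent is present, so its curve is
    the *conditional* presence probability given the parent.
    """

    name: str
    p50: float
    p95: float
    parent: str | None = None

    def __post_init__(self):
        if not (0 <= self.p50 < self.p95):
            raise ValueError(f"{self.name}: need 0 <= p50 < p95")

    @property
    def curve(self) -> LogisticCurve:
        return LogisticCurve.from_thresholds(self.name, self.p50, self.p95)


#: Default generating curves.  cTnT dp2, desmin dp1 and calpain 1 dp use the
#: published total-group thresholds; desmin dp2's conditional curve uses the
#: published age-corrected thresholds (the only regression available for it).
#: cTnT dp1 and desmin dp3 have no published regression ("few cases"): dp1's
#: curve encodes its early emergence (2 of its 3 absences sat at ADD 2.6 and
#: 3.1 °d), dp3's its late, last-in-chain appearance (8/40 cases).
DEFAULT_MARKERS: tuple[MarkerSpec, ...] = (
    MarkerSpec("ctnt_dp1", 2.0, 6.0),
    MarkerSpec("ctnt_dp2", 9.4, 28.2),
    MarkerSpec("desmin_dp1", 6.7, 28.1),
    MarkerSpec("desmin_dp2", 9.0, 23.3, parent="desmin_dp1"),
    MarkerSpec("desmin_dp3", 18.0, 36.0, parent="desmin_dp2"),
    MarkerSpec("calpain1_dp", 15.0, 39.6),
)

_CAUSE_CLASSES = ("internal", "trauma", "intoxication", "unknown")
_CAUSE_PROBS = (27 / 40, 10 / 40, 1 / 40, 2 / 40)


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-generator settings; defaults reproduce the study conditions.

    ``extreme_slope_factor`` < 1 attenuates every marker's slope (around an
    unchanged P50) for demographically extreme cases — age outside (18, 80)
    or BMI outside (19, 30) — emulating the noisier degradation observed in
    the very young/old and under-/overweight.  The default 1.0 disables the
    effect so the cohort is generated from the clean per-product curves.
    """

    n_cases: int = 40
    seed: int = 0
    pmi_h: TruncNormal = TruncNormal(37.7, 27.8, 4.0, 92.8)
    #: PMI range for cases never brought into cooling; bodies found late are
    #: cooled, so uncooled cases skew short
    pmi_h_uncooled: TruncNormal = TruncNormal(37.7, 27.8, 4.0, 36.0)
    #: longest time a body stays at scene ambient before discovery/cooling
    max_scene_h: float = 24.0
    ambient_temp_c: TruncNormal = TruncNormal(19.8, 4.6, -7.0, 21.0)
    cooling_fraction: float = 28 / 40
    cooling_temp_c: float = 4.0
    cooling_time_h: TruncNormal = TruncNormal(39.1, 26.3, 0.5, 88.0)
    age_y: TruncNormal = TruncNormal(69.1, 19.5, 2.0, 90.0)
    bmi: TruncNormal = TruncNormal(26.2, 6.1, 10.7, 50.4)
    female_fraction: float = 23 / 40
    markers: tuple[MarkerSpec, ...] = DEFAULT_MARKERS
    extreme_slope_factor: float = 1.0

    def validate(self) -> None:
        if self.n_cases < 0:
            raise ValueError("n_cases must be >= 0")
        for frac in (self.cooling_fraction, self.female_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must be in [0, 1]")
        if not 0 < self.extreme_slope_factor <= 1:
            raise ValueError("extreme_slope_factor must be in (0, 1]")
        names = [m.name for m in self.markers]
        if len(names) != len(set(names)):
            raise ValueError("duplicate marker names")
        for m in self.markers:
            if m.parent is not None and m.parent not in names:
                raise ValueError(f"{m.name}: unknown parent {m.parent!r}")
            if m.curve.beta1 <= 0:
                raise ValueError(f"{m.name}: slope must be positive")


@dataclass
class SyntheticCase:
    """One generated case with its ground truth attached."""

    id: str
    age: float
    bmi: float
    sex: str
    cause_class: str
    pmi_h: float
    profile: TemperatureProfile
    true_add: float
    true_presence: dict[str, int]

    @property
    def demographically_extreme(self) -> bool:
        return not (18 < self.age < 80) or not (19 < self.bmi < 30)


def generate_cohort(
    config: GeneratorConfig = GeneratorConfig(), seed: int | None = None
) -> list[SyntheticCase]:
    """Draw a cohort; deterministic given the (config's or overriding) seed."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cases = []
    for i in range(config.n_cases):
        cooled = rng.random() < config.cooling_fraction
        pmi = float(
            (config.pmi_h if cooled else config.pmi_h_uncooled).sample(rng)
        )
        ambient = float(config.ambient_temp_c.sample(rng))
        if cooled:
            cool = min(float(config.cooling_time_h.sample(rng)), pmi)
            # cooling begins at discovery: scene time is capped
            cool = max(cool, pmi - config.max_scene_h)
            pairs = [(pmi - cool, ambient), (cool, config.cooling_temp_c)]
        else:
            pairs = [(pmi, ambient)]
        profile = TemperatureProfile.from_pairs(pairs, label=f"case-{i + 1:03d}")
        add = compute_add(profile, pmi)
        age = float(config.age_y.sample(rng))
        bmi = float(config.bmi.sample(rng))
        sex = "F" if rng.random() < config.female_fraction else "M"
        cause = str(rng.choice(_CAUSE_CLASSES, p=_CAUSE_PROBS))
        extreme = not (18 < age < 80) or not (19 < bmi < 30)

        presence: dict[str, int] = {}
        for m in config.markers:
            if m.parent is not None and presence.get(m.parent) != 1:
                presence[m.name] = 0
                continue
            curve = m.curve
            b1 = curve.beta1
            if extreme and config.extreme_slope_factor < 1:
                b1 *= config.extreme_slope_factor  # same P50, shallower curve
            p = float(1 / (1 + math.exp(-b1 * (add - m.p50))))
            presence[m.name] = int(rng.random() < p)

        cases.append(
            SyntheticCase(
                id=f"case-{i + 1:03d}",
                age=age,
                bmi=bmi,
                sex=sex,
                cause_class=cause,
                pmi_h=pmi,
                profile=profile,
                true_add=add,
                true_presence=presence,
            )
        )
    return cases


def cohort_frame(cases: Sequence[SyntheticCase]) -> pd.DataFrame:
    """Flat DataFrame of covariates, true ADD, and true presence columns."""
    marker_names = list(cases[0].true_presence) if cases else []
    rows = []
    for c in cases:
        row = {
            "id": c.id,
            "age": c.age,
            "bmi": c.bmi,
            "sex": c.sex,
            "cause_class": c.cause_class,
            "pmi_h": c.pmi_h,
            "add": c.true_add,
        }
        row.update({m: c.true_presence[m] for m in marker_names})
        rows.append(row)
    cols = ["id", "age", "bmi", "sex", "cause_class", "pmi_h", "add", *marker_names]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Lane-trace synthesis
# ---------------------------------------------------------------------------

#: nominal peak centers, kDa for blot assays
_BLOT_PEAKS_KDA = {
    "tropomyosin": {"tropomyosin_native": (36.5, 37.5)},
    "ctnt": {"ctnt_native": (43.0, 47.0), "ctnt_dp1": (38.0,), "ctnt_dp2": (33.0,)},
    "desmin": {
        "desmin_native": (47.0, 50.0, 53.0),
        "desmin_dp1": (38.0,),
        "desmin_dp2": (35.0,),
        "desmin_dp3": (32.0,),
    },
}
#: peak centers in lane-position units for the (ladder-less) zymogram
_ZYM_PEAKS_POS = {
    "calpain1_native": (43.0,),
    "calpain1_dp": (51.0,),
    "calpain2_native": (59.0,),
}

_LADDER_KDA = (250.0, 150.0, 100.0, 75.0, 50.0, 37.0, 25.0, 20.0, 15.0, 10.0)


def standard_ladder() -> LadderCalibration:
    """A conventional 10-point pre-stained ladder laid out log-linearly
    between lane positions 5 and 95."""
    logs = np.log10(_LADDER_KDA)
    pos = 5.0 + 90.0 * (logs[0] - logs) / (logs[0] - logs[-1])
    return LadderCalibration(zip(pos, _LADDER_KDA))


@dataclass(frozen=True)
class TraceConfig:
    """Lane-trace synthesis settings.

    ``noise_sd`` is the additive Gaussian noise level in intensity units;
    with the default native-band area of 1000 and peak width 0.35 position
    units, the weakest allowed product peak (5 % of the dominant area) has
    height ~57, so noise_sd = 0.5 corresponds to a signal-to-noise ratio of
    about 114 for that peak.  ``forced_area_frac`` pins named products to an
    exact fraction of the dominant band (for threshold studies).
    """

    grid_step: float = 0.1
    peak_sigma: float = 0.35
    native_area: float = 1000.0
    product_area_frac: tuple[float, float] = (0.05, 0.8)
    noise_sd: float = 0.5
    drift_amp: float = 1.0
    drift_period: float = 60.0
    forced_area_frac: Mapping[str, float] | None = None

    def min_product_height(self) -> float:
        frac = self.product_area_frac[0]
        return frac * self.native_area / (self.peak_sigma * math.sqrt(2 * math.pi))

    def snr(self) -> float:
        """Signal-to-noise: weakest product peak height over noise sd."""
        return math.inf if self.noise_sd == 0 else (
            self.min_product_height() / self.noise_sd
        )


def _render_lane(
    peak_centers: Sequence[tuple[float, float]],  # (position, area)
    config: TraceConfig,
    rng: np.random.Generator,
    ladder: LadderCalibration | None,
    label: str,
) -> LaneTrace:
    pos = np.arange(0.0, 100.0 + config.grid_step / 2, config.grid_step)
    signal = np.zeros_like(pos)
    s = config.peak_sigma
    for center, area in peak_centers:
        signal += (
            area / (s * math.sqrt(2 * math.pi))
            * np.exp(-0.5 * ((pos - center) / s) ** 2)
        )
    if config.drift_amp > 0:
        phase = rng.uniform(0, 2 * math.pi)
        signal += config.drift_amp * 0.5 * (
            1 + np.sin(2 * math.pi * pos / config.drift_period + phase)
        )
    if config.noise_sd > 0:
        signal += rng.normal(0.0, config.noise_sd, size=pos.shape)
    return LaneTrace(pos, np.clip(signal, 0.0, None), ladder=ladder, label=label)


def generate_lane_traces(
    case: SyntheticCase,
    panel: Panel | None = None,
    config: TraceConfig = TraceConfig(),
    seed: int = 0,
) -> dict[str, LaneTrace]:
    """Render one case's marker vector as per-assay densitometric traces.

    Native bands are always drawn (total area = ``native_area`` split over
    the band multiplet); each present product gets a Gaussian peak whose
    area is a random fraction of the dominant band, at least 5 % of it.
    Deterministic given ``seed`` and the case id.
    """
    panel = panel or default_panel()
    # per-case substream so cohort-level trace generation is order-independent
    rng = np.random.default_rng(np.random.SeedSequence([seed, *case.id.encode()]))
    ladder = standard_ladder()
    traces: dict[str, LaneTrace] = {}
    for assay in panel.assays:
        zym = assay.name == "zymography"
        peaks: list[tuple[float, float]] = []
        for product in assay.products:
            if zym:
                centers = _ZYM_PEAKS_POS[product.name]
            else:
                centers_kda = _BLOT_PEAKS_KDA[assay.name][product.name]
                centers = tuple(ladder.mw_to_position(k) for k in centers_kda)
            if product.role == "native":
                area = config.native_area
            else:
                if case.true_presence.get(product.name) != 1:
                    continue
                forced = (config.forced_area_frac or {}).get(product.name)
                frac = (
                    forced
                    if forced is not None
                    else rng.uniform(*config.product_area_frac)
                )
                area = frac * config.native_area
            for c in centers:
                peaks.append((c, area / len(centers)))
        traces[assay.name] = _render_lane(
            peaks, config, rng, None if zym else ladder,
            label=f"{case.id}/{assay.name}",
        )
    return traces


# ---------------------------------------------------------------------------
# File round trip
# ---------------------------------------------------------------------------

def cohort_to_files(
    cases: Sequence[SyntheticCase],
    out_dir,
    panel: Panel | None = None,
    traces: bool = False,
    trace_config: TraceConfig = TraceConfig(),
    seed: int = 0,
) -> Path:
    """Write a cohort as the pipeline's on-disk inputs.

    Layout: ``cases.csv`` (id,age,bmi,sex,cause_class,pmi_h,profile_file),
    ``profiles/<id>.csv`` temperature profiles, ``calls.csv`` (long format:
    id,product,presence), and with ``traces=True`` also ``ladder.csv`` plus
    ``traces/<id>_<assay>.csv`` lane traces.  Rewriting with the same seed
    is byte-identical.
    """
    out = Path(out_dir)
    (out / "profiles").mkdir(parents=True, exist_ok=True)
    frame = cohort_frame(cases)
    marker_names = list(cases[0].true_presence) if cases else []
    case_cols = frame[["id", "age", "bmi", "sex", "cause_class", "pmi_h"]].copy()
    case_cols["profile_file"] = [f"profiles/{c.id}.csv" for c in cases]
    case_cols.to_csv(out / "cases.csv", index=False)
    for c in cases:
        c.profile.to_csv(out / "profiles" / f"{c.id}.csv")
    calls = (
        frame.melt(
            id_vars=["id"], value_vars=marker_names,
            var_name="product", value_name="presence",
        ).sort_values(["id", "product"], kind="stable")
        if cases
        else pd.DataFrame(columns=["id", "product", "presence"])
    )
    calls.to_csv(out / "calls.csv", index=False)
    if traces:
        panel = panel or default_panel()
        (out / "traces").mkdir(exist_ok=True)
        standard_ladder_df = pd.DataFrame(
            {
                "position": standard_ladder().positions,
                "mw_kda": standard_ladder().mw_kda,
            }
        )
        standard_ladder_df.to_csv(out / "ladder.csv", index=False)
        for c in cases:
            for assay, trace in generate_lane_traces(
                c, panel=panel, config=trace_config, seed=seed
            ).items():
                trace.to_csv(out / "traces" / f"{c.id}_{assay}.csv")
    return out


def read_cohort(in_dir) -> tuple[pd.DataFrame, dict[str, TemperatureProfile], pd.DataFrame]:
    """Read back what :func:`cohort_to_files` wrote.

    Returns (case table with recomputed ``add``, profiles by case id,
    wide calls table indexed like the case table).
    """
    root = Path(in_dir)
    cases = pd.read_csv(root / "cases.csv")
    profiles = {
        row["id"]: TemperatureProfile.from_csv(root / row["profile_file"])
        for _, row in cases.iterrows()
    }
    if len(cases):
        cases["add"] = [
            compute_add(profiles[i], p) for i, p in zip(cases["id"], cases["pmi_h"])
        ]
    else:
        cases["add"] = pd.Series(dtype=float)
    calls_long = pd.read_csv(root / "calls.csv")
    calls = (
        calls_long.pivot(index="id", columns="product", values="presence")
        .reindex(cases["id"])
        .reset_index()
        if len(calls_long)
        else pd.DataFrame({"id": cases["id"]})
    )
    calls.columns.name = None
    return cases, profiles, calls
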