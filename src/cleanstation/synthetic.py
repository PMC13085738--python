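"""Synthetic cleaning-mutualism studies with known ground truth.

Emulates a before/during/after habitat-manipulation experiment at goby
cleaning stations: 20 stations split 10/5/5 into experimental,
experimental-control (sham) and control groups, each surveyed four
times (before, first, second, after).  Clean and pose events arrive as
homogeneous Poisson processes whose rates carry station-level lognormal
heterogeneity and treatment-by-replicate effect factors; clean
durations are lognormal; client identities are drawn from a
station-specific multinomial over a reef fish species pool; one-frame-
per-minute censuses track tagged individuals; flight-initiation-
distance (FID) trials receive an additive treatment shift plus Gaussian
noise.  The effect profile used is retained on the dataset as ground
truth for parameter-recovery experiments.

The default effect scenario encodes a recoverable behavioural decline:
cleaning rate, clean duration and posing drop to 60% of baseline while
the manipulation is in place and return to baseline afterwards, while
FID (a fear/boldness proxy) rises by 3 cm and stays elevated.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .rugosity import SurfaceProfile

__all__ = [
    "StudyDesign",
    "Baselines",
    "EffectProfile",
    "StudyDataset",
    "simulate_study",
    "make_profile",
    "DEFAULT_SPECIES_POOL",
    "TREATMENTS",
    "REPLICATES",
]

TREATMENTS = ("experimental", "experimental_control", "control")
REPLICATES = ("before", "first", "second", "after")

#: Caribbean patch-reef client pool: 26 species across 16 families.
DEFAULT_SPECIES_POOL = (
    ("Acanthurus coeruleus", "Acanthuridae"),
    ("Acanthurus tractus", "Acanthuridae"),
    ("Acanthurus chirurgus", "Acanthuridae"),
    ("Stegastes partitus", "Pomacentridae"),
    ("Stegastes adustus", "Pomacentridae"),
    ("Abudefduf saxatilis", "Pomacentridae"),
    ("Sparisoma viride", "Scaridae"),
    ("Sparisoma aurofrenatum", "Scaridae"),
    ("Scarus iseri", "Scaridae"),
    ("Haemulon flavolineatum", "Haemulidae"),
    ("Haemulon sciurus", "Haemulidae"),
    ("Haemulon plumierii", "Haemulidae"),
    ("Lutjanus apodus", "Lutjanidae"),
    ("Lutjanus mahogoni", "Lutjanidae"),
    ("Ocyurus chrysurus", "Lutjanidae"),
    ("Cephalopholis cruentata", "Serranidae"),
    ("Epinephelus guttatus", "Serranidae"),
    ("Thalassoma bifasciatum", "Labridae"),
    ("Halichoeres bivittatus", "Labridae"),
    ("Chaetodon capistratus", "Chaetodontidae"),
    ("Holacanthus ciliaris", "Pomacanthidae"),
    ("Pseudupeneus maculatus", "Mullidae"),
    ("Holocentrus adscensionis", "Holocentridae"),
    ("Canthigaster rostrata", "Tetraodontidae"),
    ("Cantherhines pullus", "Monacanthidae"),
    ("Balistes vetula", "Balistidae"),
)

#: Variables that take multiplicative treatment-by-replicate factors.
FACTOR_VARIABLES = ("cleaning_rate", "clean_duration", "posing_rate", "client_abundance")


@dataclass(frozen=True)
class StudyDesign:
    """Experimental design constants of one study."""

    n_stations: int = 20
    allocation: tuple = (
        ("experimental", 10),
        ("experimental_control", 5),
        ("control", 5),
    )
    replicate_labels: tuple = REPLICATES
    obs_duration_range_min: tuple = (40.0, 104.0)
    species_pool: tuple = DEFAULT_SPECIES_POOL
    fid_trials_per_survey: int = 1
    n_fid_dropouts: int = 0  # surveys whose FID trial is unusable
    profile_span_cm: float = 40.0

    def __post_init__(self):
        total = sum(n for _, n in self.allocation)
        if total != self.n_stations:
            raise ValueError(
                f"allocation sums to {total}, expected n_stations={self.n_stations}"
            )
        if len(self.replicate_labels) != 4:
            raise ValueError("replicate_labels must have exactly 4 ordered levels")
        lo, hi = self.obs_duration_range_min
        if lo <= 0 or hi < lo:
            raise ValueError(f"invalid obs_duration_range_min={self.obs_duration_range_min}")

    @property
    def treatments(self) -> dict:
        return dict(self.allocation)


@dataclass(frozen=True)
class Baselines:
    """Grand-mean behaviour levels an average station expresses at baseline.

    Defaults follow typical Caribbean neon-goby stations: a handful of
    cleans per hour lasting on the order of ten seconds, slightly more
    frequent client posing, FID around 10 cm and a few tens of potential
    clients passing per hour.
    """

    clean_rate_per_hr: float = 4.65
    clean_duration_mean_s: float = 13.1
    clean_duration_sdlog: float = 0.8
    pose_rate_per_hr: float = 7.34
    fid_cm: float = 10.75
    client_abundance_per_hr: float = 40.0
    frame_presence_mean: float = 3.0  # mean frames an individual stays visible

    def __post_init__(self):
        for name in (
            "clean_rate_per_hr",
            "clean_duration_mean_s",
            "pose_rate_per_hr",
            "fid_cm",
            "client_abundance_per_hr",
            "frame_presence_mean",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"baseline parameter {name} must be positive")


def _factor_key(variable: str, treatment: str, replicate: str) -> tuple:
    return (variable, treatment, replicate)


@dataclass(frozen=True)
class EffectProfile:
    """Treatment-by-replicate effects applied to station baselines.

    ``factors`` maps (variable, treatment, replicate) to a positive
    multiplicative factor (rates, durations, abundance); unlisted cells
    default to 1.  ``fid_shift_cm`` maps (treatment, replicate) to an
    additive FID shift in cm, defaulting to 0.  ``station_sd`` is the SD
    of the lognormal station-level baseline multiplier (mean-one
    parameterisation, so expected rates equal the baseline means);
    ``residual_sd_cm`` is the within-station FID noise SD.
    """

    factors: tuple = ()  # ((variable, treatment, replicate), factor) pairs
    fid_shift_cm: tuple = ()  # ((treatment, replicate), shift) pairs
    station_sd: float = 0.35
    residual_sd_cm: float = 2.25
    baselines: Baselines = field(default_factory=Baselines)

    def __post_init__(self):
        for (v, t, r), f in self.factors:
            if f <= 0:
                raise ValueError(f"factor for {(v, t, r)} must be positive, got {f}")
        if self.station_sd < 0:
            raise ValueError("station_sd must be non-negative")
        if self.residual_sd_cm < 0:
            raise ValueError("residual_sd_cm must be non-negative")

    def factor(self, variable: str, treatment: str, replicate: str) -> float:
        return dict(self.factors).get(_factor_key(variable, treatment, replicate), 1.0)

    def fid_shift(self, treatment: str, replicate: str) -> float:
        return dict(self.fid_shift_cm).get((treatment, replicate), 0.0)

    @classmethod
    def null(cls, station_sd: float = 0.35, residual_sd_cm: float = 2.25, **kw):
        """No treatment effects anywhere; only heterogeneity and noise."""
        return cls(station_sd=station_sd, residual_sd_cm=residual_sd_cm, **kw)

    @classmethod
    def default_decline(cls, decline: float = 0.4, fid_shift: float = 3.0, **kw):
        """Recoverable behavioural decline with a persistent FID shift.

        Behaviours drop to ``1 - decline`` of baseline at the two
        during-manipulation replicates and recover fully afterwards;
        FID shifts up by ``fid_shift`` cm and stays up at 'after'.
        """
        f = 1.0 - decline
        factors = tuple(
            ((v, "experimental", r), f)
            for v in ("cleaning_rate", "clean_duration", "posing_rate")
            for r in ("first", "second")
        )
        shifts = tuple(
            (("experimental", r), fid_shift) for r in ("first", "second", "after")
        )
        return cls(factors=factors, fid_shift_cm=shifts, **kw)


@dataclass
class StudyDataset:
    """A complete simulated study plus the truth that generated it."""

    stations: pd.DataFrame
    surveys: pd.DataFrame
    clean_events: pd.DataFrame
    pose_events: pd.DataFrame
    frame_censuses: pd.DataFrame
    fid_trials: pd.DataFrame
    profiles: dict  # station_id -> SurfaceProfile
    truth: tuple  # (StudyDesign, EffectProfile, seed)

    def to_csv_dir(self, outdir) -> None:
        """Write the observation CSVs plus a truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in (
            "stations",
            "surveys",
            "clean_events",
            "pose_events",
            "frame_censuses",
            "fid_trials",
        ):
            getattr(self, name).to_csv(outdir / f"{name}.csv", index=False)
        prof = pd.concat(
            [
                pd.DataFrame(
                    {"station_id": sid, "x_cm": p.x_cm, "z_cm": p.z_cm}
                )
                for sid, p in self.profiles.items()
            ],
            ignore_index=True,
        )
        prof.to_csv(outdir / "profiles.csv", index=False)
        design, effects, seed = self.truth
        truth = {
            "seed": seed,
            "design": dataclasses.asdict(design),
            "effects": dataclasses.asdict(effects),
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1, default=list))


def make_profile(
    span_cm: float, roughness: float, seed: int, n_levels: int = 8
) -> SurfaceProfile:
    """Random rough transect by midpoint displacement.

    ``roughness`` in [0, 1] scales the displacement amplitude relative
    to the span; 0 gives an exactly flat profile (rugosity 1), and the
    expected chain rugosity decreases monotonically as roughness grows.
    The slow (0.8 per level) amplitude decay keeps fine-scale relief, so
    coral-head-like transects at high roughness consume several times
    their span in chain (2 cm-link rugosity roughly 0.1-0.6 over the
    default roughness range).
    """
    if span_cm <= 0:
        raise ValueError(f"span_cm must be positive, got {span_cm}")
    if not 0.0 <= roughness <= 1.0:
        raise ValueError(f"roughness must lie in [0, 1], got {roughness}")
    rng = np.random.default_rng(seed)
    x = np.array([0.0, float(span_cm)])
    z = np.zeros(2)
    scale = roughness * span_cm
    for _ in range(n_levels):
        xm = 0.5 * (x[:-1] + x[1:])
        zm = 0.5 * (z[:-1] + z[1:]) + rng.normal(0.0, scale, size=xm.size)
        nx = np.empty(x.size + xm.size)
        nz = np.empty_like(nx)
        nx[0::2], nx[1::2] = x, xm
        nz[0::2], nz[1::2] = z, zm
        x, z = nx, nz
        scale *= 0.8
    return SurfaceProfile(x, z)


def _station_table(design: StudyDesign, rng: np.random.Generator) -> pd.DataFrame:
    labels = np.repeat(
        [t for t, _ in design.allocation], [n for _, n in design.allocation]
    )
    treatments = rng.permutation(labels)
    ids = [f"S{i + 1:02d}" for i in range(design.n_stations)]
    return pd.DataFrame(
        {
            "station_id": ids,
            "treatment": treatments,
            "depth_m": np.round(rng.uniform(0.5, 5.0, design.n_stations), 2),
            "n_cleaners": 1 + rng.poisson(0.7, design.n_stations),
            "surface_area_m2": np.round(
                np.exp(rng.normal(np.log(6.0), 1.0, design.n_stations)), 2
            ),
        }
    )


def simulate_study(
    design: StudyDesign, effects: EffectProfile, seed: int
) -> StudyDataset:
    """Generate one full study; byte-identical for identical inputs.

    Every station-replicate pair yields exactly one survey record, so a
    default design emits 20 x 4 = 80 surveys.
    """
    rng = np.random.default_rng(seed)
    base = effects.baselines
    stations = _station_table(design, rng)
    profiles = {
        sid: make_profile(
            design.profile_span_cm,
            float(rng.uniform(0.4, 1.0)),
            int(rng.integers(0, 2**31 - 1)),
        )
        for sid in stations["station_id"]
    }

    # station-level lognormal multipliers, mean-one so E[rate] = baseline
    sd = effects.station_sd
    mu_adj = -0.5 * sd * sd
    n = design.n_stations
    mult = {
        v: np.exp(rng.normal(mu_adj, sd, n)) if sd > 0 else np.ones(n)
        for v in ("rate", "duration", "pose", "fid", "abundance")
    }
    # station-specific client community: Dirichlet around a lognormal pool profile
    pool = design.species_pool
    pool_w = np.exp(rng.normal(0.0, 1.0, len(pool)))
    pool_w /= pool_w.sum()
    station_probs = rng.dirichlet(pool_w * 30.0, size=n)
    species = np.array([s for s, _ in pool])
    families = np.array([f for _, f in pool])

    surveys, cleans, poses, frames, fids = [], [], [], [], []
    lo, hi = design.obs_duration_range_min

    for si, st in stations.iterrows():
        sid, trt = st["station_id"], st["treatment"]
        probs = station_probs[si]
        for rep in design.replicate_labels:
            dur_min = float(rng.uniform(lo, hi))
            hours = dur_min / 60.0
            dur_s = dur_min * 60.0
            surveys.append(
                {
                    "station_id": sid,
                    "replicate": rep,
                    "treatment": trt,
                    "obs_duration_min": dur_min,
                }
            )

            # clean events: Poisson count, uniform starts, lognormal durations
            lam = (
                base.clean_rate_per_hr
                * mult["rate"][si]
                * effects.factor("cleaning_rate", trt, rep)
            )
            k = rng.poisson(lam * hours)
            starts = np.sort(rng.uniform(0.0, dur_s, k))
            mean_dur = (
                base.clean_duration_mean_s
                * mult["duration"][si]
                * effects.factor("clean_duration", trt, rep)
            )
            mlog = np.log(mean_dur) - 0.5 * base.clean_duration_sdlog**2
            durations = rng.lognormal(mlog, base.clean_duration_sdlog, k)
            sp_idx = rng.choice(len(pool), size=k, p=probs)
            for j in range(k):
                cleans.append(
                    {
                        "station_id": sid,
                        "replicate": rep,
                        "start_s": round(starts[j], 2),
                        "end_s": round(starts[j] + durations[j], 2),
                        "client_species": species[sp_idx[j]],
                        "client_family": families[sp_idx[j]],
                        "n_cleaners": int(
                            min(st["n_cleaners"], 1 + rng.poisson(0.3))
                        ),
                    }
                )

            # pose events
            lam_p = (
                base.pose_rate_per_hr
                * mult["pose"][si]
                * effects.factor("posing_rate", trt, rep)
            )
            kp = rng.poisson(lam_p * hours)
            times = np.sort(rng.uniform(0.0, dur_s, kp))
            psp = rng.choice(len(pool), size=kp, p=probs)
            for j in range(kp):
                poses.append(
                    {
                        "station_id": sid,
                        "replicate": rep,
                        "time_s": round(times[j], 2),
                        "client_species": species[psp[j]],
                    }
                )

            # frame censuses: tagged individuals visible over short windows
            n_frames = max(int(dur_min), 1)
            lam_a = (
                base.client_abundance_per_hr
                * mult["abundance"][si]
                * effects.factor("client_abundance", trt, rep)
            )
            n_ind = rng.poisson(lam_a * hours)
            ind_sp = rng.choice(len(pool), size=n_ind, p=probs)
            first_frame = rng.integers(1, n_frames + 1, size=n_ind)
            stay = 1 + rng.poisson(base.frame_presence_mean - 1.0, size=n_ind)
            for j in range(n_ind):
                tag = f"{sid}-{rep}-i{j + 1:03d}"
                for fr in range(
                    first_frame[j], min(first_frame[j] + stay[j], n_frames + 1)
                ):
                    frames.append(
                        {
                            "station_id": sid,
                            "replicate": rep,
                            "frame_index": int(fr),
                            "individual_tag": tag,
                            "species": species[ind_sp[j]],
                            "family": families[ind_sp[j]],
                        }
                    )

            # FID trials
            shift = effects.fid_shift(trt, rep)
            for j in range(design.fid_trials_per_survey):
                val = (
                    base.fid_cm * mult["fid"][si]
                    + shift
                    + rng.normal(0.0, effects.residual_sd_cm)
                )
                fids.append(
                    {
                        "station_id": sid,
                        "replicate": rep,
                        "cleaner_id": f"{sid}-c{j + 1}",
                        "fid_cm": round(max(val, 0.0), 2),
                        "note": "",
                    }
                )

    fid_df = pd.DataFrame(fids)
    if design.n_fid_dropouts > 0 and len(fid_df):
        drop = rng.choice(len(fid_df), size=design.n_fid_dropouts, replace=False)
        fid_df.loc[drop, "fid_cm"] = np.nan
        fid_df.loc[drop, "note"] = "poor_footage"

    cols_clean = [
        "station_id", "replicate", "start_s", "end_s",
        "client_species", "client_family", "n_cleaners",
    ]
    cols_pose = ["station_id", "replicate", "time_s", "client_species"]
    cols_frame = [
        "station_id", "replicate", "frame_index", "individual_tag", "species", "family",
    ]
    return StudyDataset(
        stations=stations,
        surveys=pd.DataFrame(surveys),
        clean_events=pd.DataFrame(cleans, columns=cols_clean),
        pose_events=pd.DataFrame(poses, columns=cols_pose),
        frame_censuses=pd.DataFrame(frames, columns=cols_frame),
        fid_trials=fid_df,
        profiles=profiles,
        truth=(design, effects, seed),
    )
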