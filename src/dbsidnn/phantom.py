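"""Synthetic five-class lesion cohorts with ground truth.

The generator emulates a multi-contrast MS study: for each lesion a
class-conditional profile supplies lesion-level means (one hierarchy level),
per-voxel jitter is added, diffusion-weighted signals are synthesized from
the spectrum forward model, and Rician noise is applied at a stated b0 SNR.
Normalized T1/T2 intensities and MTR are drawn directly from the profile.

Class-conditional parameter values are *invented* — the source data are not
deposited and only histogram shapes are known — but they are constrained by
documented qualitative orderings: NAWM has the highest fiber fraction and
MTR; PBH the lowest fiber fraction and the most free water; PGH sits between
PBH and NBH; AGH carries an elevated restricted fraction (inflammatory
cellularity). Overlap between adjacent classes is deliberate: no single
feature separates the classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.stats import norm, truncnorm

from .acquisition import AcquisitionScheme, VoxelSignal, make_default_scheme
from .contrasts import CLASSES, LesionRecord
from .dbsi import B_D_SCALE
from .errors import ValidationError

#: arbitrary scanner-unit CSF b0 intensity used as the normalization baseline
CSF_B0 = 1000.0


@dataclass(frozen=True)
class MetricSpec:
    """Generative law for one scalar metric: lesion-level truncated normal
    plus independent per-voxel normal jitter."""

    mean: float
    lesion_sd: float
    voxel_sd: float
    lo: float = -np.inf
    hi: float = np.inf

    def lesion_dist(self):
        a = (self.lo - self.mean) / self.lesion_sd
        b = (self.hi - self.mean) / self.lesion_sd
        return truncnorm(a, b, loc=self.mean, scale=self.lesion_sd)

    def draw_lesion_mean(self, rng) -> float:
        return float(self.lesion_dist().rvs(random_state=rng))

    def voxel_density(self, x):
        """Marginal voxel-level density (lesion law convolved with jitter)."""
        m = np.linspace(
            max(self.lo, self.mean - 6 * self.lesion_sd),
            min(self.hi, self.mean + 6 * self.lesion_sd),
            801,
        )
        pm = self.lesion_dist().pdf(m)
        x = np.atleast_1d(np.asarray(x, dtype=float))
        px = norm.pdf(x[:, None], loc=m[None, :], scale=self.voxel_sd)
        return integrate.trapezoid(px * pm[None, :], m, axis=1)


@dataclass(frozen=True)
class PhantomClassProfile:
    """Generative distributions for one lesion class."""

    name: str
    fiber_fraction: MetricSpec
    lambda_par: MetricSpec
    lambda_perp: MetricSpec
    restricted: MetricSpec
    hindered: MetricSpec
    free: MetricSpec
    mtr: MetricSpec
    t1_ir: MetricSpec
    t2_ir: MetricSpec
    b0_norm: MetricSpec
    lesion_size_mean: float          # voxels per lesion (lognormal mean)
    lesion_size_sigma: float = 0.5   # lognormal shape
    enhancing: bool = False
    persistent_12mo: bool = False
    t2_hyperintense: bool = False

    @property
    def flags(self) -> dict:
        return {
            "enhancing": self.enhancing,
            "persistent_12mo": self.persistent_12mo,
            "t2_hyperintense": self.t2_hyperintense,
        }


def default_profiles() -> dict[str, PhantomClassProfile]:
    """The five class profiles used as study conditions.

    T1-IR truncation bounds sit strictly inside each class's IR band, so the
    lesion-level IR always reproduces its class under the IR labeler, while
    the much larger per-voxel T1 jitter makes the voxel-level distributions
    of adjacent classes overlap heavily.
    """
    def spec(mean, lsd, vsd, lo=-np.inf, hi=np.inf):
        return MetricSpec(mean, lsd, vsd, lo, hi)

    common = dict(lesion_size_sigma=0.5)
    return {
        "PBH": PhantomClassProfile(
            name="PBH",
            fiber_fraction=spec(0.25, 0.09, 0.07, 0.02, 0.60),
            lambda_par=spec(1.35, 0.12, 0.08, 0.8, 2.6),
            lambda_perp=spec(0.65, 0.09, 0.06, 0.15, 1.2),
            restricted=spec(0.10, 0.06, 0.05, 0.0, 1.0),
            hindered=spec(0.30, 0.06, 0.05, 0.0, 1.0),
            free=spec(0.35, 0.06, 0.04, 0.0, 1.0),
            mtr=spec(17.0, 3.5, 2.5, 2.0, 45.0),
            t1_ir=spec(1.35, 0.18, 0.35, 1.05, 1.68),
            t2_ir=spec(1.20, 0.12, 0.15, 0.3, 2.5),
            b0_norm=spec(0.85, 0.06, 0.05, 0.2, 1.5),
            lesion_size_mean=108.3,
            persistent_12mo=True, t2_hyperintense=True,
            **common,
        ),
        "PGH": PhantomClassProfile(
            name="PGH",
            fiber_fraction=spec(0.38, 0.09, 0.07, 0.05, 0.75),
            lambda_par=spec(1.45, 0.12, 0.08, 0.8, 2.6),
            lambda_perp=spec(0.58, 0.09, 0.06, 0.15, 1.2),
            restricted=spec(0.12, 0.06, 0.05, 0.0, 1.0),
            hindered=spec(0.30, 0.06, 0.05, 0.0, 1.0),
            free=spec(0.18, 0.06, 0.04, 0.0, 1.0),
            mtr=spec(22.0, 3.5, 2.5, 2.0, 45.0),
            t1_ir=spec(2.15, 0.18, 0.35, 1.75, 2.55),
            t2_ir=spec(1.10, 0.12, 0.15, 0.3, 2.5),
            b0_norm=spec(0.80, 0.06, 0.05, 0.2, 1.5),
            lesion_size_mean=66.5,
            persistent_12mo=True, t2_hyperintense=True,
            **common,
        ),
        "AGH": PhantomClassProfile(
            name="AGH",
            fiber_fraction=spec(0.38, 0.09, 0.07, 0.05, 0.75),
            lambda_par=spec(1.45, 0.12, 0.08, 0.8, 2.6),
            lambda_perp=spec(0.58, 0.09, 0.06, 0.15, 1.2),
            restricted=spec(0.26, 0.06, 0.05, 0.0, 1.0),
            hindered=spec(0.10, 0.06, 0.05, 0.0, 1.0),
            free=spec(0.24, 0.06, 0.04, 0.0, 1.0),
            mtr=spec(24.0, 3.5, 2.5, 2.0, 45.0),
            t1_ir=spec(2.15, 0.18, 0.35, 1.75, 2.55),
            t2_ir=spec(1.15, 0.12, 0.15, 0.3, 2.5),
            b0_norm=spec(0.80, 0.06, 0.05, 0.2, 1.5),
            lesion_size_mean=141.1,
            enhancing=True, t2_hyperintense=True,
            **common,
        ),
        "NBH": PhantomClassProfile(
            name="NBH",
            fiber_fraction=spec(0.55, 0.09, 0.07, 0.10, 0.85),
            lambda_par=spec(1.55, 0.12, 0.08, 0.8, 2.6),
            lambda_perp=spec(0.50, 0.09, 0.06, 0.15, 1.2),
            restricted=spec(0.12, 0.06, 0.05, 0.0, 1.0),
            hindered=spec(0.23, 0.06, 0.05, 0.0, 1.0),
            free=spec(0.10, 0.05, 0.04, 0.0, 1.0),
            mtr=spec(28.0, 3.5, 2.5, 2.0, 45.0),
            t1_ir=spec(3.00, 0.20, 0.35, 2.65, 4.00),
            t2_ir=spec(1.05, 0.12, 0.15, 0.3, 2.5),
            b0_norm=spec(0.75, 0.06, 0.05, 0.2, 1.5),
            lesion_size_mean=60.6,
            t2_hyperintense=True,
            **common,
        ),
        "NAWM": PhantomClassProfile(
            name="NAWM",
            fiber_fraction=spec(0.72, 0.08, 0.06, 0.30, 0.95),
            lambda_par=spec(1.65, 0.12, 0.08, 0.8, 2.6),
            lambda_perp=spec(0.35, 0.08, 0.06, 0.10, 1.0),
            restricted=spec(0.08, 0.045, 0.035, 0.0, 1.0),
            hindered=spec(0.15, 0.045, 0.035, 0.0, 1.0),
            free=spec(0.05, 0.03, 0.025, 0.0, 1.0),
            mtr=spec(33.0, 3.5, 2.5, 2.0, 45.0),
            t1_ir=spec(3.20, 0.20, 0.35, 2.70, 4.20),
            t2_ir=spec(0.75, 0.10, 0.12, 0.3, 2.5),
            b0_norm=spec(0.65, 0.06, 0.05, 0.2, 1.5),
            lesion_size_mean=120.9,
            **common,
        ),
    }


def default_composition() -> dict[str, int]:
    """Lesion counts per class matching the emulated study (499 total)."""
    return {"PBH": 92, "PGH": 89, "AGH": 16, "NBH": 189, "NAWM": 113}


def single_feature_bayes_error(
    prof_a: PhantomClassProfile, prof_b: PhantomClassProfile, metric: str = "t1_ir"
) -> float:
    """Bayes error of the optimal single-feature classifier between two
    classes (equal priors), by numeric integration of the voxel-level
    marginal densities."""
    sa: MetricSpec = getattr(prof_a, metric)
    sb: MetricSpec = getattr(prof_b, metric)
    lo = min(sa.mean - 6 * (sa.lesion_sd + sa.voxel_sd), sb.mean - 6 * (sb.lesion_sd + sb.voxel_sd))
    hi = max(sa.mean + 6 * (sa.lesion_sd + sa.voxel_sd), sb.mean + 6 * (sb.lesion_sd + sb.voxel_sd))
    x = np.linspace(lo, hi, 2001)
    pa = sa.voxel_density(x)
    pb = sb.voxel_density(x)
    return float(integrate.trapezoid(0.5 * np.minimum(pa, pb), x))


# ---------------------------------------------------------------------------
# Noise
# ---------------------------------------------------------------------------

def _rician(values: np.ndarray, sigma, rng) -> np.ndarray:
    n1 = rng.normal(0.0, 1.0, size=values.shape)
    n2 = rng.normal(0.0, 1.0, size=values.shape)
    sigma = np.asarray(sigma, dtype=float)
    return np.sqrt((values + sigma * n1) ** 2 + (sigma * n2) ** 2)


def add_rician_noise(signal: VoxelSignal, snr: float, rng) -> VoxelSignal:
    """Magnitude-MR noise: each value v becomes sqrt((v+n1)^2 + n2^2) with
    n1, n2 ~ N(0, sigma^2) and sigma = b0_mean / snr. ``snr = inf`` is a
    no-op."""
    if not snr > 0:
        raise ValidationError(f"snr must be > 0, got {snr}")
    if np.isinf(snr):
        return signal
    sigma = signal.b0_mean / snr
    noisy = _rician(signal.values, sigma, rng)
    return VoxelSignal(values=noisy, b0_mean=signal.b0_mean, index=signal.index)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """Ground-truthed phantom dataset: lesion records, a per-voxel truth
    table, and the raw (noisy) DWI signal block."""

    scheme: AcquisitionScheme
    lesions: list
    voxels: pd.DataFrame
    signals: np.ndarray
    seed: int
    snr: float

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    @property
    def n_lesions(self) -> int:
        return len(self.lesions)

    def lesion_frame(self) -> pd.DataFrame:
        from .contrasts import LesionTable

        return LesionTable(self.lesions).to_frame()

    def measured_b0(self) -> np.ndarray:
        """Per-voxel mean b0 intensity of the noisy signals."""
        return self.signals[:, self.scheme.b0_mask].mean(axis=1)

    def feature_table(self, dbsi_source: str = "truth", fit_config=None) -> pd.DataFrame:
        """Per-voxel feature rows for the classifier experiments.

        ``dbsi_source="truth"`` takes the DBSI metrics from the generative
        parameters; ``"fit"`` recomputes them by running the voxel-wise
        spectral fit on the noisy signals (slower by orders of magnitude but
        exercises the full pipeline). DTI metrics are always fitted from the
        signals; normalized b0 is always the measured one.
        """
        from .dti import fit_dti_table

        v = self.voxels
        out = pd.DataFrame({"lesion_id": v["lesion_id"], "lesion_class": v["lesion_class"]})
        if dbsi_source == "truth":
            out["dbsi_fiber_fraction"] = v["fiber_fraction"]
            out["dbsi_fiber_fa"] = v["fiber_fa"]
            out["dbsi_fiber_ad"] = v["lambda_par"]
            out["dbsi_fiber_rd"] = v["lambda_perp"]
            out["dbsi_restricted_fraction"] = v["restricted_fraction"]
            out["dbsi_hindered_fraction"] = v["hindered_fraction"]
            out["dbsi_water_fraction"] = v["water_fraction"]
        elif dbsi_source == "fit":
            from .dbsi import DbsiFitConfig, fit_dbsi_voxel

            cfg = fit_config or DbsiFitConfig()
            rows = np.empty((self.n_voxels, 7))
            for i in range(self.n_voxels):
                sig = VoxelSignal.from_values(self.signals[i], self.scheme)
                _, m = fit_dbsi_voxel(sig, self.scheme, cfg)
                rows[i] = [
                    m.fiber_fraction, m.fiber_fa, m.fiber_ad, m.fiber_rd,
                    m.restricted_fraction, m.hindered_fraction, m.water_fraction,
                ]
            out[[
                "dbsi_fiber_fraction", "dbsi_fiber_fa", "dbsi_fiber_ad", "dbsi_fiber_rd",
                "dbsi_restricted_fraction", "dbsi_hindered_fraction", "dbsi_water_fraction",
            ]] = rows
        else:
            raise ValidationError(f"unknown dbsi_source {dbsi_source!r}")
        out["dbsi_b0_norm"] = self.measured_b0() / CSF_B0
        dti = fit_dti_table(self.signals / self.measured_b0()[:, None], self.scheme)
        out[["dti_adc", "dti_fa", "dti_ad", "dti_rd"]] = dti
        out["mtr"] = v["mtr"]
        out["t1_ir"] = v["t1_ir"]
        out["t2_ir"] = v["t2_ir"]
        return out

    # -- serialization ------------------------------------------------------

    def save(self, directory):
        """Write the cohort as a directory: cohort.json (metadata),
        lesions.csv, voxels.csv, signals.npy, scheme.bval/.bvec."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "seed": self.seed,
            "snr": None if np.isinf(self.snr) else self.snr,
            "n_lesions": self.n_lesions,
            "n_voxels": self.n_voxels,
        }
        (d / "cohort.json").write_text(json.dumps(meta, indent=2))
        self.lesion_frame().to_csv(d / "lesions.csv", index=False)
        self.voxels.to_csv(d / "voxels.csv", index=False)
        np.save(d / "signals.npy", self.signals)
        np.savetxt(d / "scheme.bval", self.scheme.bvalues[None, :], fmt="%.6g")
        np.savetxt(d / "scheme.bvec", self.scheme.directions.T, fmt="%.8f")

    @classmethod
    def load(cls, directory) -> "SyntheticCohort":
        d = Path(directory)
        meta = json.loads((d / "cohort.json").read_text())
        bvals = np.loadtxt(d / "scheme.bval").ravel()
        bvecs = np.loadtxt(d / "scheme.bvec").T
        scheme = AcquisitionScheme(directions=bvecs, bvalues=bvals)
        lesion_df = pd.read_csv(d / "lesions.csv")
        lesions = [
            LesionRecord(
                lesion_id=r.lesion_id, lesion_class=r.lesion_class, ir_t1=r.ir_t1,
                enhancing=bool(r.enhancing), persistent_12mo=bool(r.persistent_12mo),
                t2_hyperintense=bool(r.t2_hyperintense), n_voxels=int(r.n_voxels),
            )
            for r in lesion_df.itertuples()
        ]
        return cls(
            scheme=scheme,
            lesions=lesions,
            voxels=pd.read_csv(d / "voxels.csv"),
            signals=np.load(d / "signals.npy"),
            seed=meta["seed"],
            snr=np.inf if meta["snr"] is None else meta["snr"],
        )


def _draw_fractions(rng, profile: PhantomClassProfile, lesion_means=None, n=None):
    """Draw (fiber, restricted, hindered, free) tuples that sum to one.

    At the lesion level the four component means are drawn once; at the voxel
    level each is jittered independently, floored, and renormalized.
    """
    specs = [profile.fiber_fraction, profile.restricted, profile.hindered, profile.free]
    if lesion_means is None:
        vals = np.array([s.draw_lesion_mean(rng) for s in specs])
        vals = np.clip(vals, 0.01, None)
        return vals / vals.sum()
    sds = np.array([s.voxel_sd for s in specs])
    vals = lesion_means[None, :] + rng.normal(0.0, 1.0, size=(n, 4)) * sds[None, :]
    vals = np.clip(vals, 0.005, None)
    return vals / vals.sum(axis=1, keepdims=True)


def generate_cohort(
    profiles: dict[str, PhantomClassProfile] | None = None,
    composition: dict[str, int] | None = None,
    voxels_per_lesion: dict[str, float] | None = None,
    scheme: AcquisitionScheme | None = None,
    snr: float = 30.0,
    seed: int = 0,
    size_scale: float = 1.0,
) -> SyntheticCohort:
    """Generate a ground-truthed phantom cohort.

    For each lesion: draw lesion-level parameter means from its class
    profile, then per-voxel values with within-lesion jitter; synthesize the
    DWI signal from the spectrum forward model (one fiber plus three
    isotropic spikes at lesion-specific restricted/hindered/free
    diffusivities); scale by the normalized-b0 draw times the CSF baseline;
    add Rician noise at the given SNR. Bit-for-bit reproducible under
    ``seed``. ``size_scale`` shrinks or grows lesion sizes for desk-scale
    runs without touching the class structure.
    """
    if not snr > 0:
        raise ValidationError(f"snr must be > 0, got {snr}")
    profiles = profiles or default_profiles()
    composition = composition or default_composition()
    for name in composition:
        if name not in profiles:
            raise ValidationError(f"composition references unknown class {name!r}")
    if any(c < 0 for c in composition.values()):
        raise ValidationError("composition counts must be >= 0")
    scheme = scheme or make_default_scheme()
    rng = np.random.default_rng(seed)

    b = scheme.bvalues[None, :] * B_D_SCALE  # (1, K)
    lesions: list[LesionRecord] = []
    voxel_frames = []
    signal_blocks = []
    lesion_counter = 0

    for cls_name in CLASSES:
        count = composition.get(cls_name, 0)
        prof = profiles[cls_name]
        size_mean = (
            voxels_per_lesion[cls_name] if voxels_per_lesion else prof.lesion_size_mean
        ) * size_scale
        mu = np.log(size_mean) - prof.lesion_size_sigma**2 / 2
        for _ in range(count):
            lesion_counter += 1
            lesion_id = f"L{lesion_counter:04d}"
            n_vox = max(3, int(round(rng.lognormal(mu, prof.lesion_size_sigma))))

            # lesion-level means
            frac_means = _draw_fractions(rng, prof)
            lpar_m = prof.lambda_par.draw_lesion_mean(rng)
            lperp_m = prof.lambda_perp.draw_lesion_mean(rng)
            mtr_m = prof.mtr.draw_lesion_mean(rng)
            t1_m = prof.t1_ir.draw_lesion_mean(rng)
            t2_m = prof.t2_ir.draw_lesion_mean(rng)
            b0_m = prof.b0_norm.draw_lesion_mean(rng)
            fiber_dir = rng.normal(size=3)
            fiber_dir /= np.linalg.norm(fiber_dir)
            d_r = rng.uniform(0.10, 0.25)
            d_h = rng.uniform(0.70, 1.40)
            d_f = rng.uniform(3.05, 3.40)

            # voxel-level draws
            fracs = _draw_fractions(rng, prof, frac_means, n_vox)  # (n, 4)
            lpar = np.clip(lpar_m + rng.normal(0, prof.lambda_par.voxel_sd, n_vox), 0.6, 2.8)
            lperp = np.clip(
                lperp_m + rng.normal(0, prof.lambda_perp.voxel_sd, n_vox), 0.10, None
            )
            lperp = np.minimum(lperp, lpar - 0.05)
            dirs = fiber_dir[None, :] + rng.normal(0, 0.05, size=(n_vox, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            mtr = np.clip(mtr_m + rng.normal(0, prof.mtr.voxel_sd, n_vox), 0.5, 60.0)
            t1 = np.clip(t1_m + rng.normal(0, prof.t1_ir.voxel_sd, n_vox), 0.05, None)
            t2 = np.clip(t2_m + rng.normal(0, prof.t2_ir.voxel_sd, n_vox), 0.05, None)
            b0n = np.clip(b0_m + rng.normal(0, prof.b0_norm.voxel_sd, n_vox), 0.05, None)

            # normalized signal synthesis (one fiber + three isotropic spikes)
            cos2 = (dirs @ scheme.directions.T) ** 2  # (n, K)
            aniso = np.exp(-b * lperp[:, None]) * np.exp(-b * (lpar - lperp)[:, None] * cos2)
            s = fracs[:, 0:1] * aniso
            s = s + fracs[:, 1:2] * np.exp(-b * d_r)
            s = s + fracs[:, 2:3] * np.exp(-b * d_h)
            s = s + fracs[:, 3:4] * np.exp(-b * d_f)
            raw = s * (b0n[:, None] * CSF_B0)
            if np.isfinite(snr):
                sigma = (b0n * CSF_B0 / snr)[:, None]
                raw = _rician(raw, sigma, rng)

            fa = (lpar - lperp) / np.sqrt(lpar**2 + 2 * lperp**2)
            voxel_frames.append(pd.DataFrame({
                "lesion_id": lesion_id,
                "lesion_class": cls_name,
                "fiber_fraction": fracs[:, 0],
                "restricted_fraction": fracs[:, 1],
                "hindered_fraction": fracs[:, 2],
                "water_fraction": fracs[:, 3],
                "lambda_par": lpar,
                "lambda_perp": lperp,
                "fiber_fa": fa,
                "b0_norm": b0n,
                "t1_ir": t1,
                "t2_ir": t2,
                "mtr": mtr,
                "d_restricted": d_r,
                "d_hindered": d_h,
                "d_free": d_f,
            }))
            signal_blocks.append(raw)
            lesions.append(LesionRecord(
                lesion_id=lesion_id,
                lesion_class=cls_name,
                ir_t1=float(t1_m),
                n_voxels=n_vox,
                **prof.flags,
            ))

    voxels = pd.concat(voxel_frames, ignore_index=True)
    signals = np.vstack(signal_blocks)
    return SyntheticCohort(
        scheme=scheme, lesions=lesions, voxels=voxels, signals=signals,
        seed=seed, snr=snr,
    )
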