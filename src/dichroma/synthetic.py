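"""Synthetic reflectance spectra with the field study's sampling design.

Generates a full spectrophotometry dataset — 13 males and 12 females, ten
body regions with region-specific per-individual spectra counts — whose
color-patch structure mirrors the qualitative findings in the study
system: orange/red male venters against UV-rich white female venters,
male blue/green/yellow flank scales, a yellow male cloacal patch, black
chest scales, and dull brown dorsal ground color shared by the sexes.

Each color patch class is a parametric archetype (long-pass logistic for
orange/red/yellow, Gaussian band for blue/green, flat-high with a UV
shoulder for UV-white, flat-low for black). A spectrum is drawn by
jittering the archetype's spectral position, applying multiplicative
noise, and clamping to [0, 1]. Regions whose male and female archetype
mixtures differ carry planted dichromatism; the generator emits a
ground-truth manifest naming them, which is the recovery surface for the
detector tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ParameterError, RegionNotFoundError
from .spectra_io import DEFAULT_WL, REGIONS, SpectrumSet, concat
from . import visual_model as vm

#: Spectra per individual per body region (the study's sampling design).
REGION_COUNTS = {
    "Abdomen": 16,
    "Chest": 8,
    "Throat": 16,
    "Cloaca": 16,
    "Dorsum": 42,
    "Flanks": 84,
    "Head": 20,
    "Legs": 16,
    "Mouth": 10,
    "Head profile": 20,
}


def _gauss(wl, center, width):
    return np.exp(-(((wl - center) / width) ** 2))


def _logistic(wl, mid, rate):
    return 1.0 / (1.0 + np.exp(-(wl - mid) / rate))


@dataclass(frozen=True)
class PatchArchetype:
    """Parametric base shape of one color-patch class.

    ``baseline`` is a flat reflectance floor; a long-pass logistic edge
    (mid/rate/height) builds orange-red-yellow type spectra; a Gaussian
    band (center/width/height) builds blue/green; ``uv_peak_height`` adds
    a 350-nm shoulder (UV-white). ``jitter_nm`` shifts edge and band
    positions per spectrum; ``noise_sd`` is multiplicative lognormal
    reflectance noise per wavelength.
    """

    name: str
    baseline: float = 0.05
    longpass_mid: float | None = None
    longpass_rate: float = 18.0
    longpass_height: float = 0.0
    band_center: float | None = None
    band_width: float = 45.0
    band_height: float = 0.0
    uv_peak_height: float = 0.0
    jitter_nm: float = 3.0
    noise_sd: float = 0.02

    def base_curve(self, wl: np.ndarray, shift: float = 0.0) -> np.ndarray:
        wl = np.asarray(wl, float)
        r = np.full_like(wl, self.baseline)
        if self.longpass_mid is not None and self.longpass_height:
            r = r + self.longpass_height * _logistic(
                wl, self.longpass_mid + shift, self.longpass_rate
            )
        if self.band_center is not None and self.band_height:
            r = r + self.band_height * _gauss(
                wl, self.band_center + shift, self.band_width
            )
        if self.uv_peak_height:
            r = r + self.uv_peak_height * _gauss(wl, 350.0 + shift, 40.0)
        return np.clip(r, 0.0, 1.0)


#: The packaged archetype library.
ARCHETYPES: dict[str, PatchArchetype] = {
    a.name: a
    for a in (
        PatchArchetype("uv_white", baseline=0.55, uv_peak_height=0.30),
        PatchArchetype("orange", longpass_mid=580.0, longpass_rate=16.0,
                       longpass_height=0.70),
        PatchArchetype("red", longpass_mid=615.0, longpass_rate=13.0,
                       longpass_height=0.70),
        PatchArchetype("yellow", longpass_mid=515.0, longpass_rate=20.0,
                       longpass_height=0.70),
        PatchArchetype("blue", band_center=460.0, band_width=45.0,
                       band_height=0.45),
        PatchArchetype("green", band_center=535.0, band_width=40.0,
                       band_height=0.45),
        PatchArchetype("black", baseline=0.04),
        PatchArchetype("brown", baseline=0.03, longpass_mid=600.0,
                       longpass_rate=60.0, longpass_height=0.25),
        # extreme outlier class used to exercise singleton removal
        PatchArchetype("uv_spike", baseline=0.02, uv_peak_height=0.9,
                       jitter_nm=8.0),
    )
}


def make_patch_spectrum(archetype: PatchArchetype, rng: np.random.Generator,
                        wl: np.ndarray = DEFAULT_WL) -> np.ndarray:
    """Draw one spectrum: jittered base curve x lognormal noise, clamped."""
    shift = rng.normal(0.0, archetype.jitter_nm) if archetype.jitter_nm else 0.0
    base = archetype.base_curve(wl, shift)
    if archetype.noise_sd:
        base = base * np.exp(rng.normal(0.0, archetype.noise_sd, wl.size))
    return np.clip(base, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Study design


# Region x sex archetype mixtures of the "paper_like" scenario. Regions
# where the two sexes share a mixture are null (no dichromatism).
_PAPER_LIKE_MIXTURES: dict[str, dict[str, dict[str, float]]] = {
    "Abdomen": {"M": {"orange": 0.6, "uv_white": 0.4},
                "F": {"uv_white": 1.0}},
    "Chest": {"M": {"orange": 0.4, "black": 0.25, "uv_white": 0.35},
              "F": {"uv_white": 1.0}},
    "Throat": {"M": {"red": 0.55, "uv_white": 0.45},
               "F": {"uv_white": 1.0}},
    "Cloaca": {"M": {"yellow": 0.5, "uv_white": 0.5},
               "F": {"uv_white": 1.0}},
    "Flanks": {"M": {"blue": 0.3, "green": 0.2, "yellow": 0.2, "brown": 0.3},
               "F": {"brown": 1.0}},
    "Dorsum": {"M": {"brown": 1.0}, "F": {"brown": 1.0}},
    "Head": {"M": {"brown": 1.0}, "F": {"brown": 1.0}},
    "Legs": {"M": {"brown": 1.0}, "F": {"brown": 1.0}},
    "Mouth": {"M": {"uv_white": 0.5, "brown": 0.5},
              "F": {"uv_white": 0.5, "brown": 0.5}},
    "Head profile": {"M": {"uv_white": 0.3, "brown": 0.7},
                     "F": {"uv_white": 0.3, "brown": 0.7}},
}


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design + archetype mixtures of a simulated study."""

    n_males: int = 13
    n_females: int = 12
    region_counts: dict = field(default_factory=lambda: dict(REGION_COUNTS))
    mixtures: dict = field(
        default_factory=lambda: {r: {s: dict(m) for s, m in d.items()}
                                 for r, d in _PAPER_LIKE_MIXTURES.items()}
    )
    outlier_rate: float = 0.0
    outlier_archetype: str = "uv_spike"
    archetypes: dict = field(default_factory=lambda: dict(ARCHETYPES))

    def __post_init__(self):
        if self.n_males < 1 or self.n_females < 1:
            raise ParameterError("need at least one individual per sex")
        for region, d in self.mixtures.items():
            if region not in self.region_counts:
                raise ParameterError(f"mixture for unknown region {region!r}")
            for sex, mix in d.items():
                total = sum(mix.values())
                if abs(total - 1.0) > 1e-9:
                    raise ParameterError(
                        f"mixture weights for {region}/{sex} sum to {total}"
                    )
                for name in mix:
                    if name not in self.archetypes:
                        raise ParameterError(f"unknown archetype {name!r}")
        for region, c in self.region_counts.items():
            if c < 1:
                raise ParameterError(f"count for {region!r} must be positive")

    @property
    def individuals(self) -> list[tuple[str, str]]:
        return ([(f"M{i + 1:02d}", "M") for i in range(self.n_males)]
                + [(f"F{i + 1:02d}", "F") for i in range(self.n_females)])

    @property
    def planted_regions(self) -> dict[str, str]:
        """Regions whose sexes draw from different mixtures, mapped to
        the sex holding the exclusive archetype(s)."""
        out = {}
        for region, d in self.mixtures.items():
            if d["M"] != d["F"]:
                m_only = set(d["M"]) - set(d["F"])
                f_only = set(d["F"]) - set(d["M"])
                out[region] = "M" if m_only or not f_only else "F"
        return out

    @classmethod
    def paper_like(cls, scale: float = 1.0,
                   outlier_rate: float = 0.0) -> "StudyDesign":
        """The default scenario (full design at scale=1). ``scale``
        shrinks the per-region spectra counts for quick runs."""
        counts = {r: max(4, round(c * scale)) for r, c in REGION_COUNTS.items()}
        return cls(region_counts=counts, outlier_rate=outlier_rate)

    @classmethod
    def null(cls, scale: float = 1.0) -> "StudyDesign":
        """Both sexes share every mixture: no dichromatism anywhere."""
        mixtures = {r: {"M": {"brown": 1.0}, "F": {"brown": 1.0}}
                    for r in REGION_COUNTS}
        counts = {r: max(4, round(c * scale)) for r, c in REGION_COUNTS.items()}
        return cls(region_counts=counts, mixtures=mixtures)

    def with_mixture(self, region: str, male: dict, female: dict) -> "StudyDesign":
        mixtures = {r: {s: dict(m) for s, m in d.items()}
                    for r, d in self.mixtures.items()}
        mixtures[region] = {"M": dict(male), "F": dict(female)}
        return replace(self, mixtures=mixtures)


# ---------------------------------------------------------------------------
# Simulation


def simulate_region(design: StudyDesign, region: str,
                    rng: np.random.Generator,
                    wl: np.ndarray = DEFAULT_WL) -> SpectrumSet:
    """Simulate one region: every individual contributes the design's
    per-region number of spectra, drawn from its sex's archetype mixture
    (plus optional outlier contamination)."""
    if region not in design.mixtures:
        raise RegionNotFoundError(f"region {region!r} not in design")
    count = design.region_counts[region]
    cols, meta_rows = [], []
    for ind_id, sex in design.individuals:
        mix = design.mixtures[region][sex]
        names = sorted(mix)
        weights = np.array([mix[n] for n in names])
        picks = rng.choice(names, size=count, p=weights / weights.sum())
        if design.outlier_rate > 0:
            out_mask = rng.random(count) < design.outlier_rate
            picks = np.where(out_mask, design.outlier_archetype, picks)
        for i, name in enumerate(picks):
            cols.append(make_patch_spectrum(design.archetypes[name], rng, wl))
            meta_rows.append({
                "spectrum_id": f"{region.replace(' ', '_')}.{ind_id}.{i:03d}",
                "individual_id": ind_id,
                "sex": sex,
                "region": region,
                "patch_index": i,
                "archetype": name,
            })
    return SpectrumSet(wl, np.column_stack(cols), pd.DataFrame(meta_rows))


def simulate_study(design: StudyDesign, seed: int | None = None,
                   wl: np.ndarray = DEFAULT_WL):
    """Simulate all regions.

    Returns ``(SpectrumSet, manifest)`` where the manifest records the
    seed, spectra counts, and which regions carry planted dichromatism
    (and in which sex) — the ground truth for detector recovery.
    """
    rng = np.random.default_rng(seed)
    sets = [simulate_region(design, region, rng, wl)
            for region in REGIONS if region in design.mixtures]
    full = concat(sets)
    planted = design.planted_regions
    manifest = {
        "seed": seed,
        "n_individuals": design.n_males + design.n_females,
        "n_males": design.n_males,
        "n_females": design.n_females,
        "spectra_per_individual": int(sum(design.region_counts.values())),
        "n_spectra": int(full.n_spectra),
        "planted_regions": dict(sorted(planted.items())),
        "null_regions": sorted(set(design.mixtures) - set(planted)),
        "outlier_rate": design.outlier_rate,
    }
    return full, manifest


def archetype_separation(names: list[str],
                         vs: vm.VisualSystem | None = None,
                         wl: np.ndarray = DEFAULT_WL) -> pd.DataFrame:
    """Pairwise JND separation of noise-free archetype base curves,
    max(dS, dL) per pair, under the given (default) visual system."""
    if vs is None:
        vs = vm.VisualSystem.build(wl)
    noise = vm.noise_vector(vs)
    catches = {n: vm.quantum_catch(ARCHETYPES[n].base_curve(wl), vs)
               for n in names}
    out = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            d = max(
                vm.chromatic_distance(catches[a], catches[b], noise),
                vm.achromatic_distance(catches[a], catches[b], noise),
            )
            out.loc[a, b] = out.loc[b, a] = d
    return out


def check_archetype_separation(design: StudyDesign,
                               vs: vm.VisualSystem | None = None,
                               min_jnd: float = 4.0) -> pd.DataFrame:
    """Assert that, within every region mixture, distinct archetypes are
    separated by more than ``min_jnd`` JND (fixture-build invariant).

    Returns the full separation table for inspection.
    """
    used = sorted({n for d in design.mixtures.values()
                   for mix in d.values() for n in mix})
    sep = archetype_separation(used, vs)
    for region, d in design.mixtures.items():
        names = sorted({n for mix in d.values() for n in mix})
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if sep.loc[a, b] <= min_jnd:
                    raise ParameterError(
                        f"archetypes {a!r} and {b!r} in region {region!r} "
                        f"are only {sep.loc[a, b]:.2f} JND apart (<= {min_jnd})"
                    )
    return sep
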