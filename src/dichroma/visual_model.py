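"""Tetrachromat receptor-noise visual model.

Implements quantum catches under an illuminant, the Vorobyev-Osorio
receptor-noise-limited chromatic distance (dS) and the double-cone
achromatic distance (dL), both in just-noticeable-difference (JND) units,
and full pairwise JND matrices per body region.

The model assumes discrimination is limited by photoreceptor noise: each
channel i has noise e_i = omega / sqrt(n_i), with omega the Weber fraction
of a unit-abundance channel and n_i the relative abundance of cone class i.
Contrasts are log quantum-catch ratios (Weber-Fechner), which makes dS and
dL invariant to a common rescaling of both stimuli or of the illuminant.

Diurnal lizards are tetrachromats (UVS/SWS/MWS/LWS single cones plus a
double cone used for achromatic vision). Measured cone spectral
sensitivities can be loaded from CSV; by default they are synthesised from
the Govardovskii A1 visual-pigment nomogram at configurable peak
wavelengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateInputError, ParameterError
from .spectra_io import DEFAULT_WL, SpectrumSet

CHANNELS = ("u", "s", "m", "l")

#: Default cone peak sensitivities, nm. Stand-ins for an iguanian
#: tetrachromat retina (UVS, SWS, MWS, LWS); override per species.
DEFAULT_LAMBDA_MAX = (365.0, 455.0, 495.0, 560.0)

#: Cone-proportion schemes. ``ratios`` orders (u, s, m, l); ``n_double``
#: is the relative abundance of the double cone used for dL.
#: - lws_emphasis: long-wavelength cones more abundant (typical diurnal
#:   lizard retina) — the default reporting scheme.
#: - equal: all single cones equally abundant.
#: - split_ds_dl: equal single cones for dS, but a more abundant double
#:   cone for dL.
CONE_PROPORTION_PRESETS = {
    "lws_emphasis": {"ratios": (1.0, 1.0, 1.0, 4.0), "n_double": 4.0},
    "equal": {"ratios": (1.0, 1.0, 1.0, 1.0), "n_double": 1.0},
    "split_ds_dl": {"ratios": (1.0, 1.0, 1.0, 1.0), "n_double": 2.0},
}


# ---------------------------------------------------------------------------
# Sensitivity and illuminant curves


def govardovskii_template(lambda_max: float, wl: np.ndarray) -> np.ndarray:
    """A1 visual-pigment absorbance template (alpha + beta band).

    Returns a nonnegative unimodal curve peaking at ``lambda_max``,
    normalised to unit area (trapezoid) over ``wl``.
    """
    wl = np.asarray(wl, dtype=float)
    if not wl[0] <= lambda_max <= wl[-1]:
        raise ParameterError(
            f"lambda_max {lambda_max} outside grid [{wl[0]}, {wl[-1]}]"
        )
    x = lambda_max / wl
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    lmb = 189.0 + 0.315 * lambda_max
    bandwidth = -40.5 + 0.195 * lambda_max
    beta = 0.26 * np.exp(-(((wl - lmb) / bandwidth) ** 2))
    s = alpha + beta
    return s / np.trapezoid(s, wl)


def ideal_illuminant(wl: np.ndarray) -> np.ndarray:
    """Flat (white) irradiance, mean 1."""
    return np.ones_like(np.asarray(wl, dtype=float))


def bluesky_irradiance(wl: np.ndarray, color_temp: float = 20000.0) -> np.ndarray:
    """Blue-sky-shaped irradiance: Planck photon flux at a high colour
    temperature (default 20000 K), normalised to mean 1.

    A smooth synthetic stand-in for tabulated blue-sky daylight; JND
    distances depend only on its spectral shape, not its absolute level.
    """
    wl = np.asarray(wl, dtype=float)
    lam = wl * 1e-9
    hc_over_k = 6.62607015e-34 * 2.99792458e8 / 1.380649e-23
    # photon flux ~ lam^-4 / (exp(hc/(lam k T)) - 1)
    q = lam**-4.0 / np.expm1(hc_over_k / (lam * color_temp))
    return q / q.mean()


def load_curve_csv(path, wl: np.ndarray) -> np.ndarray:
    """Load a (wl, value) CSV and interpolate onto the model grid."""
    df = pd.read_csv(path)
    return np.interp(np.asarray(wl, float), df["wl"].to_numpy(float),
                     df[df.columns[1]].to_numpy(float))


# ---------------------------------------------------------------------------
# Visual system


@dataclass(frozen=True)
class VisualSystem:
    """Cone sensitivities, illuminant, cone abundances and Weber fraction.

    ``sensitivities`` has one column per single-cone channel (u, s, m, l);
    ``double_cone`` is the achromatic channel. ``background`` is a
    reflectance curve; the default flat ("ideal") background makes von
    Kries chromatic adaptation a no-op, so it is off by default.
    """

    wavelengths: np.ndarray
    sensitivities: np.ndarray  # (n_wl, 4)
    double_cone: np.ndarray  # (n_wl,)
    illuminant: np.ndarray  # (n_wl,)
    background: np.ndarray  # (n_wl,)
    cone_ratios: np.ndarray = field(
        default_factory=lambda: np.asarray(CONE_PROPORTION_PRESETS["lws_emphasis"]["ratios"])
    )
    n_double: float = 4.0
    weber: float = 0.10
    scheme_id: str = "lws_emphasis"

    def __post_init__(self):
        for name in ("wavelengths", "sensitivities", "double_cone",
                     "illuminant", "background", "cone_ratios"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        n = self.wavelengths.size
        if self.sensitivities.shape != (n, 4):
            raise ParameterError("sensitivities must be (n_wl, 4)")
        for name in ("double_cone", "illuminant", "background"):
            if getattr(self, name).shape != (n,):
                raise ParameterError(f"{name} must match the wavelength grid")
            if np.any(getattr(self, name) < 0):
                raise ParameterError(f"{name} must be nonnegative")
        if np.any(self.sensitivities < 0):
            raise ParameterError("sensitivities must be nonnegative")
        if np.any(self.cone_ratios <= 0) or self.n_double <= 0:
            raise ParameterError("cone abundances must be positive")
        if self.weber <= 0:
            raise ParameterError("Weber fraction must be positive")

    @classmethod
    def build(
        cls,
        wl: np.ndarray | None = None,
        lambda_max: tuple = DEFAULT_LAMBDA_MAX,
        scheme: str = "lws_emphasis",
        weber: float = 0.10,
        illuminant: str | np.ndarray = "bluesky",
        background: str | np.ndarray = "ideal",
        sensitivity_csv=None,
    ) -> "VisualSystem":
        """Assemble a visual system from nomogram templates and presets.

        ``illuminant``/``background`` accept "ideal", "bluesky",
        "file:<csv>" or an explicit array; ``sensitivity_csv`` (columns
        wl, u, s, m, l[, d]) overrides the nomogram curves.
        """
        wl = DEFAULT_WL if wl is None else np.asarray(wl, float)
        if sensitivity_csv is not None:
            df = pd.read_csv(sensitivity_csv)
            sens = np.column_stack(
                [np.interp(wl, df["wl"], df[c]) for c in CHANNELS]
            )
            dbl = (np.interp(wl, df["wl"], df["d"])
                   if "d" in df.columns else sens[:, 3].copy())
        else:
            sens = np.column_stack(
                [govardovskii_template(lm, wl) for lm in lambda_max]
            )
            dbl = sens[:, 3].copy()  # double cone ~ LWS member
        if scheme not in CONE_PROPORTION_PRESETS:
            raise ParameterError(
                f"unknown cone-proportion scheme {scheme!r}; "
                f"choose from {sorted(CONE_PROPORTION_PRESETS)}"
            )
        preset = CONE_PROPORTION_PRESETS[scheme]
        return cls(
            wavelengths=wl,
            sensitivities=sens,
            double_cone=dbl,
            illuminant=_resolve_curve(illuminant, wl, kind="illuminant"),
            background=_resolve_curve(background, wl, kind="background"),
            cone_ratios=np.asarray(preset["ratios"], float),
            n_double=float(preset["n_double"]),
            weber=weber,
            scheme_id=scheme,
        )

    def with_scheme(self, scheme: str) -> "VisualSystem":
        preset = CONE_PROPORTION_PRESETS[scheme]
        return replace(
            self,
            cone_ratios=np.asarray(preset["ratios"], float),
            n_double=float(preset["n_double"]),
            scheme_id=scheme,
        )


def _resolve_curve(spec, wl, kind: str) -> np.ndarray:
    if isinstance(spec, str):
        if spec == "ideal":
            return np.ones_like(wl)
        if spec == "bluesky":
            if kind != "illuminant":
                raise ParameterError("'bluesky' is an illuminant, not a background")
            return bluesky_irradiance(wl)
        if spec.startswith("file:"):
            return load_curve_csv(spec[5:], wl)
        raise ParameterError(f"unknown {kind} spec {spec!r}")
    arr = np.asarray(spec, float)
    if arr.shape != wl.shape:
        raise ParameterError(f"{kind} array must match the wavelength grid")
    return arr


# ---------------------------------------------------------------------------
# Quantum catches


@dataclass(frozen=True)
class QuantumCatch:
    """Raw and relative quantum catches of one spectrum.

    ``raw`` orders (u, s, m, l); ``double`` is the double-cone catch;
    ``relative`` renormalises the four single cones to sum 1.
    """

    raw: np.ndarray
    double: float
    relative: np.ndarray = None

    def __post_init__(self):
        raw = np.asarray(self.raw, float)
        object.__setattr__(self, "raw", raw)
        if np.any(raw < 0) or self.double < 0:
            raise DegenerateInputError("quantum catches must be nonnegative")
        total = raw.sum()
        if self.relative is None:
            if total <= 0:
                raise DegenerateInputError(
                    "all-zero quantum catch: relative catches undefined"
                )
            object.__setattr__(self, "relative", raw / total)


def quantum_catch(R: np.ndarray, vs: VisualSystem) -> QuantumCatch:
    """Quantum catch of one reflectance spectrum:
    Q_i = integral of R * I * S_i over wavelength (trapezoid rule)."""
    R = np.asarray(R, float)
    if R.shape != vs.wavelengths.shape:
        raise ParameterError("spectrum must be on the visual-system grid")
    if not np.any(R > 0):
        raise DegenerateInputError("all-zero spectrum has no defined color")
    prod = R * vs.illuminant
    raw = np.trapezoid(prod[:, None] * vs.sensitivities, vs.wavelengths, axis=0)
    dbl = float(np.trapezoid(prod * vs.double_cone, vs.wavelengths))
    return QuantumCatch(raw=raw, double=dbl)


def quantum_catch_matrix(s: SpectrumSet, vs: VisualSystem):
    """Vectorised catches for a SpectrumSet.

    Returns ``(raw, double, relative)`` with shapes (n, 4), (n,), (n, 4).
    """
    if not np.array_equal(s.wavelengths, vs.wavelengths):
        raise ParameterError("spectra and visual system use different grids")
    prod = s.reflectance * vs.illuminant[:, None]  # (n_wl, n)
    raw = np.trapezoid(
        prod[:, :, None] * vs.sensitivities[:, None, :], vs.wavelengths, axis=0
    )
    dbl = np.trapezoid(prod * vs.double_cone[:, None], vs.wavelengths, axis=0)
    totals = raw.sum(axis=1)
    if np.any(totals <= 0):
        raise DegenerateInputError("some spectra have zero total quantum catch")
    return raw, dbl, raw / totals[:, None]


# ---------------------------------------------------------------------------
# Receptor noise and JND distances


@dataclass(frozen=True)
class NoiseVector:
    """Per-channel noise e_i = weber / sqrt(n_i), plus the double cone's."""

    e: np.ndarray
    e_double: float

    def __post_init__(self):
        object.__setattr__(self, "e", np.asarray(self.e, float))
        if np.any(self.e <= 0) or self.e_double <= 0:
            raise ParameterError("noise must be positive")


def noise_vector(vs: VisualSystem) -> NoiseVector:
    if np.any(vs.cone_ratios <= 0) or vs.n_double <= 0:
        raise ParameterError("cone abundances must be positive")
    return NoiseVector(
        e=vs.weber / np.sqrt(vs.cone_ratios),
        e_double=vs.weber / np.sqrt(vs.n_double),
    )


def _receptor_noise_distance(delta_f: np.ndarray, e: np.ndarray) -> float:
    """General N-receptor receptor-noise distance.

    dS^2 = sum_{i<j} (prod_{k != i,j} e_k)^2 (df_i - df_j)^2
           / sum_i (prod_{k != i} e_k)^2
    """
    e = np.asarray(e, float)
    n = e.size
    e2 = e**2
    prod_all = np.prod(e2)
    num = 0.0
    for i, j in combinations(range(n), 2):
        w = prod_all / (e2[i] * e2[j])
        num += w * (delta_f[i] - delta_f[j]) ** 2
    den = np.sum(prod_all / e2)
    return float(np.sqrt(num / den))


def chromatic_distance(Qa: QuantumCatch, Qb: QuantumCatch,
                       noise: NoiseVector) -> float:
    """Receptor-noise chromatic distance dS in JND.

    Contrasts are df_i = ln(Q_i^a / Q_i^b); symmetric in its arguments and
    invariant to common rescaling of both catches.
    """
    if np.any(Qa.raw <= 0) or np.any(Qb.raw <= 0):
        raise DegenerateInputError("zero quantum catch: log contrast undefined")
    delta_f = np.log(Qa.raw / Qb.raw)
    return _receptor_noise_distance(delta_f, noise.e)


def achromatic_distance(Qa: QuantumCatch, Qb: QuantumCatch,
                        noise: NoiseVector) -> float:
    """Achromatic (luminance) distance dL = |ln(Q_D^a / Q_D^b)| / e_D."""
    if Qa.double <= 0 or Qb.double <= 0:
        raise DegenerateInputError("zero double-cone catch")
    return float(abs(np.log(Qa.double / Qb.double)) / noise.e_double)


# ---------------------------------------------------------------------------
# Pairwise matrices


@dataclass(frozen=True)
class DistanceMatrix:
    """Pairwise chromatic (dS) and achromatic (dL) JND matrices for the
    pooled spectra of one body region (no grouping by sex or individual)."""

    ids: list
    dS: np.ndarray
    dL: np.ndarray
    region: str
    meta: pd.DataFrame = None

    def __post_init__(self):
        for name in ("dS", "dL"):
            m = np.asarray(getattr(self, name), float)
            object.__setattr__(self, name, m)
            if m.shape != (len(self.ids), len(self.ids)):
                raise ParameterError(f"{name} shape does not match ids")

    def channel(self, which: str) -> np.ndarray:
        if which not in ("dS", "dL"):
            raise ParameterError(f"channel must be 'dS' or 'dL', got {which!r}")
        return getattr(self, which)


def _log_contrast_coords(raw: np.ndarray, e: np.ndarray):
    """Embed log catches so that euclidean distance equals dS.

    With f = ln Q, df_i - df_j for a pair of stimuli equals
    g_ij(a) - g_ij(b) where g_ij = f_i - f_j. dS is therefore a weighted
    euclidean distance in the 6-dimensional space of channel differences.
    """
    f = np.log(raw)
    e2 = np.asarray(e, float) ** 2
    prod_all = np.prod(e2)
    den = np.sum(prod_all / e2)
    cols, weights = [], []
    for i, j in combinations(range(e2.size), 2):
        cols.append(f[:, i] - f[:, j])
        weights.append(prod_all / (e2[i] * e2[j]) / den)
    G = np.column_stack(cols) * np.sqrt(weights)
    return G


def pairwise_distances(s: SpectrumSet, vs: VisualSystem,
                       region: str) -> DistanceMatrix:
    """Full symmetric dS and dL matrices over all spectra of a region,
    pooled across individuals and sexes."""
    sub = s.region(region)
    if sub.n_spectra < 2:
        raise DegenerateInputError(
            f"region {region!r} has {sub.n_spectra} spectrum; need >= 2"
        )
    raw, dbl, _ = quantum_catch_matrix(sub, vs)
    if np.any(raw <= 0) or np.any(dbl <= 0):
        raise DegenerateInputError("zero quantum catches in region")
    noise = noise_vector(vs)
    G = _log_contrast_coords(raw, noise.e)
    dS = squareform(pdist(G, metric="euclidean"))
    fD = np.log(dbl)
    dL = np.abs(fD[:, None] - fD[None, :]) / noise.e_double
    return DistanceMatrix(ids=sub.spectrum_ids, dS=dS, dL=dL,
                          region=region, meta=sub.meta)
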