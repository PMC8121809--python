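"""Forward generator of synthetic time-resolved difference-spectral datasets.

The generator stands in for measured flash-photolysis data: each photocycle
intermediate carries a difference spectrum composed of Gaussian or Lorentzian
bands (positive photoproduct bands, negative educt bleaches), and the dataset
is the population-weighted superposition

    ΔE(ν̃, t) = Σ_states P_state(t) · spectrum_state(ν̃)  +  noise,

optionally with homo- or heteroscedastic Gaussian noise drawn from an
explicitly seeded generator.  Because the populations of a first-order network
are sums of exponentials, every noiseless trace lies exactly inside the
multi-exponential model class of the global fit.

The default FTIR model emulates the GtACR1 anion-channelrhodopsin photocycle:
the branched K → {L₁, L₁′} → L₂ → M ⇌ → N/O → ground scheme with apparent
half-lives 450 ns, 18 µs, 1.9 ms, 35 ms, 107 ms and 4.4 s, and the marker-band
structure established for this protein —

* +1184 cm⁻¹  protonated 13-*cis* retinal: present while the Schiff base is
  protonated (K through L₂), gone in M;
* −1529 cm⁻¹  ground-state retinal C=C bleach in all intermediates;
* −1644 cm⁻¹  amide-I backbone change developing with channel opening and
  recovering with closing;
* +1691 cm⁻¹  conducting-state marker, present only in the open L₂ state;
* 1708(−)/1716(+) cm⁻¹  protonated-Glu-68 carbonyl pair, the bleach from K
  onward and the up-shifted product band from L₂ onward;
* no band at 1154 cm⁻¹ in any state — this protein shows no C=N-*syn*
  (light-adapted) species.

Absolute ΔE amplitudes are declared conventions chosen to reproduce the
qualitative band hierarchy (the N/O spectrum is weak, scaled ×0.1); they are
not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from collections.abc import Iterable, Mapping

import numpy as np

from .dataset import SpectralDataset, Spectrum
from .kinetics import (
    GROUND,
    GTACR1_FTIR_HALFLIVES,
    GTACR1_UVVIS_HALFLIVES,
    KineticScheme,
    PARALLEL,
    populations,
    rate_from_halflife,
    scheme_from_dict,
    scheme_to_dict,
    solve_l2_m_rates,
)

__all__ = [
    "Band",
    "PhotocycleModel",
    "band_profile",
    "species_difference_spectrum",
    "default_gtacr1_model",
    "default_gtacr1_uvvis_model",
    "default_ftir_axis",
    "default_uvvis_axis",
    "default_time_grid",
    "simulate_dataset",
    "simulate_uvvis",
    "shift_bands",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
]

_FOUR_LN2 = 4.0 * np.log(2.0)


@dataclass(frozen=True)
class Band:
    """One spectral band: signed peak height at ``center`` with width ``fwhm``."""

    center: float
    fwhm: float
    amplitude: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if not self.fwhm > 0:
            raise ValueError("fwhm must be positive")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown band shape {self.shape!r}")


def band_profile(band: Band, axis) -> np.ndarray:
    """Evaluate one band on a channel axis; the peak value equals ``amplitude``."""
    x = np.asarray(axis, dtype=float)
    d = x - band.center
    if band.shape == "gaussian":
        return band.amplitude * np.exp(-_FOUR_LN2 * d * d / (band.fwhm**2))
    half = band.fwhm / 2.0
    return band.amplitude * half * half / (d * d + half * half)


def species_difference_spectrum(bands: Iterable[Band], axis, label: str = "") -> Spectrum:
    """Sum of band profiles: one intermediate's difference spectrum vs ground."""
    x = np.asarray(axis, dtype=float)
    total = np.zeros_like(x)
    for band in bands:
        total += band_profile(band, x)
    return Spectrum(axis=x.copy(), values=total, label=label)


@dataclass
class PhotocycleModel:
    """A kinetic scheme plus per-state band-composed difference spectra.

    Every non-ground state must have a ``species_spectra`` entry; an empty band
    list marks a spectrally silent state.
    """

    scheme: KineticScheme
    species_spectra: dict[str, tuple[Band, ...]]

    def __post_init__(self) -> None:
        spectra = {s: tuple(b) for s, b in self.species_spectra.items()}
        for s in spectra:
            if s not in self.scheme.states or s == GROUND:
                raise ValueError(f"species spectrum for invalid state {s!r}")
        missing = [s for s in self.scheme.nonground_states if s not in spectra]
        if missing:
            raise ValueError(f"states without a species spectrum entry: {missing}")
        self.species_spectra = spectra

    def state_spectrum(self, state: str, axis) -> Spectrum:
        return species_difference_spectrum(
            self.species_spectra[state], axis, label=f"{state} - ground"
        )


# ---------------------------------------------------------------------------
# default GtACR1 models
# ---------------------------------------------------------------------------

def default_ftir_axis(step: float = 2.0) -> np.ndarray:
    """1100–1800 cm⁻¹ fingerprint-to-carbonyl axis at step-scan-like spacing."""
    return np.arange(1100.0, 1800.0 + 0.5 * step, step)


def default_uvvis_axis(step: float = 2.0) -> np.ndarray:
    """330–650 nm visible axis."""
    return np.arange(330.0, 650.0 + 0.5 * step, step)


def default_time_grid(n: int = 120, t_min: float = 1e-7, t_max: float = 20.0) -> np.ndarray:
    """Log-spaced delay times emulating merged step-scan + rapid-scan coverage."""
    return np.geomspace(t_min, t_max, n)


# Declared default amplitudes (ΔE); the 1529 cm⁻¹ bleach sets the reference scale.
_RETINAL_13CIS = Band(1184.0, 8.0, +0.6)
_GROUND_CC_BLEACH = Band(1529.0, 8.0, -1.0)
_K_ETHYLENIC = Band(1515.0, 10.0, +0.5)  # red-shifted C=C of the early K product
_AMIDE_I = Band(1644.0, 12.0, -0.5)
_AMIDE_I_HALF = Band(1644.0, 12.0, -0.25)
_CONDUCTING = Band(1691.0, 8.0, +0.35)
_GLU68_BLEACH = Band(1708.0, 8.0, -0.25)
_GLU68_PRODUCT = Band(1716.0, 8.0, +0.25)

_CLOSED_L_BANDS = (_RETINAL_13CIS, _GROUND_CC_BLEACH, _GLU68_BLEACH)
_NO_SCALE = 0.1


def _scaled(bands: tuple[Band, ...], factor: float) -> tuple[Band, ...]:
    return tuple(replace(b, amplitude=b.amplitude * factor) for b in bands)


def _gtacr1_scheme(halflives, reverse_ratio: float, branching_fraction: float) -> KineticScheme:
    k = [rate_from_halflife(h) for h in halflives]
    k_fwd, _, k_m = solve_l2_m_rates(k[3], k[4], reverse_ratio)
    return PARALLEL.build(
        k_K=k[0],
        phi=branching_fraction,
        k_open_fast=k[1],
        k_open_slow=k[2],
        k_close=k_fwd,
        reverse_ratio=reverse_ratio,
        k_m_decay=k_m,
        k_recovery=k[5],
    )


def default_gtacr1_model(
    reverse_ratio: float = 0.3, branching_fraction: float = 0.7
) -> PhotocycleModel:
    """The default FTIR ground truth: GtACR1 photocycle with Fig.-2-style bands.

    The scheme is the parallel-branch topology whose apparent half-lives equal
    the six FTIR transition values (450 ns … 4.4 s) by construction: the
    L₂ ⇌ M ⟶ N/O edge rates are solved from the two closing half-lives and the
    reversibility ratio, so changing ``reverse_ratio`` leaves the observable
    kinetics unchanged.  ``reverse_ratio=0`` gives the fully irreversible
    chain required by the species-spectrum reconstruction route.
    """
    scheme = _gtacr1_scheme(GTACR1_FTIR_HALFLIVES, reverse_ratio, branching_fraction)
    spectra = {
        # K is spectrally distinct from L: its red-shifted ethylenic product
        # band decays with T1, making the K -> L transition observable
        "K": _CLOSED_L_BANDS + (_K_ETHYLENIC,),
        "L1": _CLOSED_L_BANDS,
        "L1p": _CLOSED_L_BANDS,
        "L2": (
            _RETINAL_13CIS,
            _GROUND_CC_BLEACH,
            _AMIDE_I,
            _CONDUCTING,
            _GLU68_BLEACH,
            _GLU68_PRODUCT,
        ),
        # Schiff base deprotonated: the 1184 cm⁻¹ marker is gone in M
        "M": (_GROUND_CC_BLEACH, _AMIDE_I_HALF, _GLU68_BLEACH, _GLU68_PRODUCT),
        "NO": _scaled((_GROUND_CC_BLEACH, _AMIDE_I, _GLU68_BLEACH), _NO_SCALE),
    }
    spectra = {s: b for s, b in spectra.items() if s in scheme.states}
    return PhotocycleModel(scheme=scheme, species_spectra=spectra)


def default_gtacr1_uvvis_model(
    reverse_ratio: float = 0.3, branching_fraction: float = 0.7
) -> PhotocycleModel:
    """UV/VIS counterpart on a nm axis with the UV/VIS transition half-lives.

    The visible bands are generic rhodopsin-like placeholders (ground bleach
    near 515 nm, red-shifted K/L products, a blue-shifted M-like product near
    390 nm); the source study names no λmax values for this protein, so only
    the kinetics carry meaning here.  The three L states are given slightly
    different product amplitudes so that every transition remains observable.
    """
    scheme = _gtacr1_scheme(GTACR1_UVVIS_HALFLIVES, reverse_ratio, branching_fraction)
    bleach = Band(515.0, 50.0, -1.0)
    spectra = {
        "K": (bleach, Band(560.0, 50.0, +0.55)),
        "L1": (bleach, Band(540.0, 45.0, +0.40)),
        "L1p": (bleach, Band(540.0, 45.0, +0.46)),
        "L2": (bleach, Band(540.0, 45.0, +0.52)),
        "M": (bleach, Band(390.0, 40.0, +0.60)),
        "NO": _scaled((bleach, Band(570.0, 50.0, +0.50)), _NO_SCALE),
    }
    spectra = {s: b for s, b in spectra.items() if s in scheme.states}
    return PhotocycleModel(scheme=scheme, species_spectra=spectra)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_dataset(
    model: PhotocycleModel,
    axis=None,
    times=None,
    noise_sigma=0.0,
    seed: int | None = None,
    modality: str = "FTIR",
    segment_label: str = "merged",
) -> SpectralDataset:
    """Simulate ΔE(ν̃, t) = Σ P_state(t)·spectrum_state(ν̃) + noise.

    ``noise_sigma`` is the per-cell Gaussian noise standard deviation in ΔE
    units, either a scalar (homoscedastic) or a per-channel vector
    (heteroscedastic).  When any noise is requested an explicit ``seed`` is
    required; there is no global random state.  ``noise_sigma=0`` returns the
    exact noiseless forward model.
    """
    if axis is None:
        axis = default_uvvis_axis() if modality == "UVVIS" else default_ftir_axis()
    axis = np.asarray(axis, dtype=float)
    if times is None:
        times = default_time_grid()
    times = np.asarray(times, dtype=float)

    states = model.scheme.nonground_states
    S = np.vstack([model.state_spectrum(s, axis).values for s in states])
    P_all = populations(model.scheme, times)
    rows = [model.scheme.index(s) for s in states]
    values = S.T @ P_all[rows]

    sigma = np.asarray(noise_sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("noise_sigma must be non-negative")
    if np.any(sigma > 0):
        if seed is None:
            raise ValueError("an explicit seed is required when noise_sigma > 0")
        rng = np.random.default_rng(seed)
        scale = sigma if sigma.ndim == 0 else sigma[:, None]
        values = values + rng.standard_normal(values.shape) * scale

    return SpectralDataset(
        axis=axis,
        times=times,
        values=values,
        modality=modality,
        segment_label=segment_label,
        axis_unit="nm" if modality == "UVVIS" else "cm-1",
    )


def simulate_uvvis(
    model: PhotocycleModel,
    wavelengths=None,
    times=None,
    noise_sigma=0.0,
    seed: int | None = None,
) -> SpectralDataset:
    """Simulate a UV/VIS transient-absorption dataset (nm axis)."""
    return simulate_dataset(
        model,
        axis=wavelengths,
        times=times,
        noise_sigma=noise_sigma,
        seed=seed,
        modality="UVVIS",
    )


def shift_bands(
    model: PhotocycleModel,
    centers: Iterable[float],
    delta: float,
    states: Iterable[str] | None = None,
) -> PhotocycleModel:
    """Shift selected band centers by ``delta`` (isotope-labelling emulation).

    Bands whose center matches one of ``centers`` (within 1e−6) are moved in
    every listed state (all states when ``states`` is None).  Only the band
    position changes — no isotope chemistry beyond the shift is modelled.
    """
    centers = [float(c) for c in centers]
    which = set(states) if states is not None else None
    new = {}
    for state, bands in model.species_spectra.items():
        if which is not None and state not in which:
            new[state] = bands
            continue
        new[state] = tuple(
            replace(b, center=b.center + delta)
            if any(abs(b.center - c) <= 1e-6 for c in centers)
            else b
            for b in bands
        )
    return PhotocycleModel(scheme=model.scheme, species_spectra=new)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def model_to_dict(model: PhotocycleModel) -> dict:
    return {
        "scheme": scheme_to_dict(model.scheme),
        "species_spectra": {
            s: [[b.center, b.fwhm, b.amplitude, b.shape] for b in bands]
            for s, bands in model.species_spectra.items()
        },
    }


def model_from_dict(d: Mapping) -> PhotocycleModel:
    spectra = {
        s: tuple(Band(c, f, a, shape) for c, f, a, shape in bands)
        for s, bands in d["species_spectra"].items()
    }
    return PhotocycleModel(scheme=scheme_from_dict(d["scheme"]), species_spectra=spectra)


def save_model(model: PhotocycleModel, path) -> None:
    import json

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model_to_dict(model), fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_model(path) -> PhotocycleModel:
    import yaml

    with open(path, encoding="utf-8") as fh:
        return model_from_dict(yaml.safe_load(fh))
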