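"""Receptor-noise-limited tetrachromatic visual modelling.

Birds see colour with four single-cone classes sensitive to very short
(VS), short (S), medium (M) and long (L) wavelengths; luminance is carried
by the double cone.  A reflectance spectrum R(lambda) viewed under an
illuminant I(lambda) produces a quantum catch per cone,

    Q_i = sum_lambda R(lambda) S_i(lambda) I(lambda) dlambda,

normalized (von Kries) by the catch of a perfect white reflector so that
q_i is illuminant-scale free.  Discriminability between two stimuli is the
receptor-noise distance of Vorobyev & Osorio over log catches
f_i = ln q_i, with per-cone noise-to-signal ratios

    omega_i = nu / sqrt(eta_i / eta_L),

where nu is the Weber fraction of the most abundant (L) cone and eta_i the
relative cone proportions.  Distances are in just-noticeable-difference
(JND) units: below 1 JND two colours are deemed indiscriminable.

The tetrachromatic chromatic distance is a positive-semidefinite quadratic
form in the log-catch differences whose null space is the all-ones vector
(uniform intensity changes are achromatic).  Its rank-3 factor embeds each
stimulus at xyz coordinates in avian colour space such that Euclidean
distance between points equals the chromatic JND distance exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from plumavis.illuminants import d65_quanta
from plumavis.spectra import GRID_5NM, ReflectanceSpectrum

CONE_ORDER = ("VS", "S", "M", "L")

#: Average violet-sensitive (V-type) cone peak sensitivities, nm.
DEFAULT_LAMBDA_MAX = (405.0, 480.0, 535.0, 565.0)
#: Average relative cone proportions VS:S:M:L.
DEFAULT_ETA = (0.38, 0.69, 1.14, 1.0)
#: Weber fraction of the L cone.
DEFAULT_NU = 0.05
#: Double-cone (achromatic channel) Weber fraction.
DEFAULT_OMEGA_D = 0.05


def govardovskii_a1(wavelengths, lambda_max: float) -> np.ndarray:
    """Govardovskii et al. A1 visual-pigment absorbance template.

    Alpha band plus beta band, evaluated at the given wavelengths (nm) for
    a pigment with peak absorbance at ``lambda_max``.  Unnormalized (the
    alpha band is ~1 at the peak by construction).
    """
    wl = np.asarray(wavelengths, dtype=float)
    x = lambda_max / wl
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    lam_b = 189.0 + 0.315 * lambda_max
    b = -40.5 + 0.195 * lambda_max
    beta = 0.26 * np.exp(-(((wl - lam_b) / b) ** 2))
    return alpha + beta


@dataclass(frozen=True)
class VisualSystem:
    """A tetrachromatic observer: sensitivities, illuminant and noise.

    Cone order is fixed as (VS, S, M, L).  Sensitivities live on the
    81-point 5-nm grid and are peak-normalized.  ``omega`` holds the
    noise-to-signal ratio per cone; ``omega[L] == nu``.
    """

    wavelengths: np.ndarray
    sensitivities: np.ndarray      # (4, 81)
    double_cone: np.ndarray        # (81,)
    illuminant: np.ndarray         # (81,), relative quanta
    lambda_max: tuple
    eta: np.ndarray                # (4,)
    nu: float
    omega: np.ndarray              # (4,)
    omega_d: float

    def __eq__(self, other):
        if not isinstance(other, VisualSystem):
            return NotImplemented
        return (
            np.array_equal(self.sensitivities, other.sensitivities)
            and np.array_equal(self.illuminant, other.illuminant)
            and np.array_equal(self.omega, other.omega)
            and self.omega_d == other.omega_d
        )


@dataclass(frozen=True)
class ConeCatch:
    """Quantum catches of one stimulus: four single cones plus double cone."""

    q: np.ndarray      # (4,) normalized catches, > 0
    f: np.ndarray      # (4,) log catches
    q_d: float         # double-cone catch
    f_d: float
    vs: VisualSystem = field(compare=False)


def compute_receptor_noise(nu: float, eta) -> np.ndarray:
    """Noise-to-signal ratio per cone: omega_i = nu / sqrt(eta_i / eta_ref).

    The reference cone is the last entry of ``eta`` (the L cone in the
    standard (VS, S, M, L) order), so omega for the reference cone equals
    the Weber fraction exactly.
    """
    eta = np.asarray(eta, dtype=float)
    if nu <= 0 or np.any(eta <= 0):
        raise ValueError("Weber fraction and cone proportions must be positive")
    return nu / np.sqrt(eta / eta[-1])


def build_visual_system(
    lambda_max=DEFAULT_LAMBDA_MAX,
    eta=DEFAULT_ETA,
    nu: float = DEFAULT_NU,
    omega_d: float = DEFAULT_OMEGA_D,
    illuminant="d65",
) -> VisualSystem:
    """Build a visual system from pigment templates on the 5-nm grid.

    Cone sensitivities are generated from the Govardovskii A1 template at
    the given peak wavelengths (defaults: average V-type vision) and
    peak-normalized.  The double-cone sensitivity is the normalized sum of
    the M and L templates.  ``illuminant`` is either "d65" (bundled CIE
    D65, converted to relative quanta) or an array on the 5-nm grid.
    """
    lambda_max = tuple(float(v) for v in lambda_max)
    if len(lambda_max) != 4:
        raise ValueError("lambda_max required for each of VS, S, M, L")
    for lm in lambda_max:
        if not (300.0 <= lm <= 700.0):
            raise ValueError(f"lambda_max {lm} nm outside [300, 700]")
    eta = np.asarray(eta, dtype=float)
    omega = compute_receptor_noise(nu, eta)

    sens = np.vstack([govardovskii_a1(GRID_5NM, lm) for lm in lambda_max])
    sens = sens / sens.max(axis=1, keepdims=True)
    dbl = sens[2] + sens[3]
    dbl = dbl / dbl.max()

    if isinstance(illuminant, str):
        if illuminant.lower() != "d65":
            raise ValueError(f"unknown illuminant {illuminant!r}")
        illum = d65_quanta()
    else:
        illum = np.asarray(illuminant, dtype=float)
        if illum.shape != GRID_5NM.shape:
            raise ValueError("illuminant must be on the 81-point 5-nm grid")
        if np.any(illum < 0) or illum.max() <= 0:
            raise ValueError("illuminant must be nonnegative with positive max")
    return VisualSystem(
        wavelengths=GRID_5NM.copy(),
        sensitivities=sens,
        double_cone=dbl,
        illuminant=illum,
        lambda_max=lambda_max,
        eta=eta,
        nu=float(nu),
        omega=omega,
        omega_d=float(omega_d),
    )


def quantum_catch(
    s: ReflectanceSpectrum, vs: VisualSystem, von_kries: bool = True
) -> ConeCatch:
    """Cone quantum catches of a reflectance spectrum under a visual system.

    The spectrum must already be on the 5-nm grid.  Reflectance is in
    percent; with von Kries normalization (default) catches are relative
    to a perfect white (100%) reflector, so a flat 100% spectrum yields
    q = 1 for every cone.
    """
    if not s.on_5nm_grid:
        raise ValueError("spectrum must be down-sampled to the 5-nm grid first")
    refl = s.reflectance / 100.0
    dl = 5.0
    q = vs.sensitivities @ (refl * vs.illuminant) * dl
    q_d = float(vs.double_cone @ (refl * vs.illuminant) * dl)
    if von_kries:
        white = vs.sensitivities @ vs.illuminant * dl
        white_d = float(vs.double_cone @ vs.illuminant * dl)
        q = q / white
        q_d = q_d / white_d
    if np.any(q <= 0) or q_d <= 0:
        zero = [CONE_ORDER[i] for i in np.nonzero(q <= 0)[0]]
        raise ValueError(f"zero catch for cone(s) {zero or ['double']}")
    return ConeCatch(q=q, f=np.log(q), q_d=q_d, f_d=float(np.log(q_d)), vs=vs)


def _check_same_system(a: ConeCatch, b: ConeCatch):
    if a.vs is not b.vs and a.vs != b.vs:
        raise ValueError("catches computed under different visual systems")


def noise_quadratic_form(omega) -> np.ndarray:
    """PSD matrix M with deltaS^2 = df' M df for the tetrachromat distance.

    M has the all-ones vector in its null space (rank 3): adding a common
    constant to all log catches leaves the chromatic distance unchanged.
    """
    w = np.asarray(omega, dtype=float)
    if w.shape != (4,):
        raise ValueError("four noise ratios required")
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    denom = sum(
        (w[i] * w[j] * w[k]) ** 2
        for i, j, k in [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
    )
    M = np.zeros((4, 4))
    for i, j in pairs:
        k, l = [c for c in range(4) if c not in (i, j)]
        d = np.zeros(4)
        d[k], d[l] = 1.0, -1.0
        M += (w[i] * w[j]) ** 2 * np.outer(d, d)
    return M / denom


def chromatic_distance(a: ConeCatch, b: ConeCatch, vs: VisualSystem | None = None) -> float:
    """Tetrachromatic receptor-noise chromatic distance, in JND."""
    _check_same_system(a, b)
    if vs is not None and not (vs is a.vs or vs == a.vs):
        raise ValueError("catches computed under a different visual system")
    df = a.f - b.f
    M = noise_quadratic_form(a.vs.omega)
    return float(np.sqrt(df @ M @ df))


def achromatic_distance(
    a: ConeCatch, b: ConeCatch, omega_d: float | None = None
) -> float:
    """Achromatic (double-cone) distance |delta f_D| / omega_D, in JND."""
    _check_same_system(a, b)
    if a.q_d <= 0 or b.q_d <= 0:
        raise ValueError("nonpositive double-cone catch")
    w = a.vs.omega_d if omega_d is None else float(omega_d)
    return abs(a.f_d - b.f_d) / w


def _embedding_factor(omega) -> np.ndarray:
    """Rank-3 factor E (3x4) of M with ||E df|| = sqrt(df' M df).

    Eigenvectors ordered by descending eigenvalue; sign fixed so each
    eigenvector's largest-magnitude entry is positive.  The convention
    makes coordinates reproducible bit-for-bit across runs.
    """
    M = noise_quadratic_form(omega)
    evals, evecs = np.linalg.eigh(M)
    order = np.argsort(evals)[::-1][:3]
    rows = []
    for idx in order:
        v = evecs[:, idx]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        rows.append(np.sqrt(max(evals[idx], 0.0)) * v)
    return np.vstack(rows)


def xyz_embed(catch: ConeCatch) -> np.ndarray:
    """Position of a stimulus in avian colour space, JND-scaled.

    Euclidean distance between embedded points equals the chromatic
    receptor-noise distance of the underlying catches.
    """
    E = _embedding_factor(catch.vs.omega)
    return E @ catch.f
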