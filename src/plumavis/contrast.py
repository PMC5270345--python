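"""Taxon-level plumage contrast against natural backgrounds.

Measurement-level colour-space coordinates are averaged in two stages —
replicates to individual, individuals to (taxon, sex) — and the Euclidean
distance from each patch's mean position to the positions of two common
natural backgrounds (green leaves; brown bark or soil) gives the chromatic
contrast in JND.  The mean of the two background contrasts is the overall
conspicuousness.  Patches are additionally classified as structurally
coloured (UV-reflective) from their mean spectrum, and per-taxon body
percentages of structural colouration are computed from region weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from plumavis.spectra import PATCHES, ReflectanceSpectrum, SpectrumCollection, downsample_5nm
from plumavis.visual_model import (
    ConeCatch,
    VisualSystem,
    quantum_catch,
    xyz_embed,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BackgroundSet:
    """The two natural backgrounds, embedded under the active visual system."""

    green: ReflectanceSpectrum
    brown: ReflectanceSpectrum
    green_xyz: np.ndarray
    brown_xyz: np.ndarray
    green_catch: ConeCatch
    brown_catch: ConeCatch
    vs: VisualSystem

    @classmethod
    def from_spectra(cls, green, brown, vs: VisualSystem) -> "BackgroundSet":
        green5 = green if green.on_5nm_grid else downsample_5nm(green)
        brown5 = brown if brown.on_5nm_grid else downsample_5nm(brown)
        gc = quantum_catch(green5, vs)
        bc = quantum_catch(brown5, vs)
        return cls(green5, brown5, xyz_embed(gc), xyz_embed(bc), gc, bc, vs)


@dataclass
class PatchMeans:
    """Per-(taxon, sex, patch) mean coordinates, catches and spectra."""

    table: pd.DataFrame            # x, y, z, f_d, n_individuals
    mean_spectra: dict             # (taxon, sex, patch) -> reflectance on 5-nm grid
    vs: VisualSystem


def aggregate_coordinates(col: SpectrumCollection, vs: VisualSystem) -> PatchMeans:
    """Two-stage mean of colour-space coordinates per (taxon, sex, patch).

    Replicate spectra are embedded individually and averaged within each
    individual, then individual means are averaged (unweighted) across
    individuals of the same sex.  The same two-stage mean is applied to
    the double-cone log catch and to the (down-sampled) reflectance, the
    latter feeding structural-colour classification.
    """
    if len(col) == 0:
        raise ValueError("empty spectrum collection")
    per_ind: dict[tuple, dict] = {}
    for key in col.keys():
        taxon, sex, ind, patch = key
        reps = col.replicates(*key)
        xyzs, fds, refls = [], [], []
        for s in reps:
            s5 = s if s.on_5nm_grid else downsample_5nm(s)
            catch = quantum_catch(s5, vs)
            xyzs.append(xyz_embed(catch))
            fds.append(catch.f_d)
            refls.append(s5.reflectance)
        cell = per_ind.setdefault((taxon, sex, patch), {"xyz": [], "fd": [], "refl": []})
        cell["xyz"].append(np.mean(xyzs, axis=0))
        cell["fd"].append(float(np.mean(fds)))
        cell["refl"].append(np.mean(refls, axis=0))

    rows, spectra = [], {}
    for (taxon, sex, patch), cell in sorted(per_ind.items()):
        xyz = np.mean(cell["xyz"], axis=0)
        rows.append({
            "taxon_id": taxon, "sex": sex, "patch": patch,
            "x": xyz[0], "y": xyz[1], "z": xyz[2],
            "f_d": float(np.mean(cell["fd"])),
            "n_individuals": len(cell["xyz"]),
        })
        spectra[(taxon, sex, patch)] = np.mean(cell["refl"], axis=0)
    table = pd.DataFrame(rows).set_index(["taxon_id", "sex", "patch"])
    return PatchMeans(table=table, mean_spectra=spectra, vs=vs)


def uv_chroma(wavelengths, reflectance) -> float:
    """Share of total reflectance in the UV band: integral over 300-400 nm
    divided by the integral over 300-700 nm (trapezoid rule)."""
    wl = np.asarray(wavelengths, dtype=float)
    r = np.asarray(reflectance, dtype=float)
    uv = wl <= 400.0 + 1e-9
    total = np.trapezoid(r, wl)
    if total <= 0:
        return 0.0
    return float(np.trapezoid(r[uv], wl[uv]) / total)


def classify_structural(wavelengths, mean_reflectance, threshold: float = 0.30) -> bool:
    """A patch is structurally coloured when its UV chroma exceeds the
    threshold (default 0.30).  A flat spectrum has UV chroma 0.25."""
    chroma = uv_chroma(wavelengths, mean_reflectance)
    decision = chroma > threshold
    logger.debug("UV chroma %.3f vs threshold %.2f -> structural=%s",
                 chroma, threshold, decision)
    return bool(decision)


def contrast_table(
    means: PatchMeans, bg: BackgroundSet, vs: VisualSystem | None = None,
    structural_threshold: float = 0.30,
) -> pd.DataFrame:
    """Per-(taxon, sex, patch) chromatic and achromatic contrasts in JND.

    Chromatic contrast is the Euclidean distance from the patch's mean
    xyz position to each background's position; achromatic contrast is
    the double-cone log-catch distance over omega_D; conspicuousness is
    the mean of the green and brown chromatic contrasts.
    """
    if vs is None:
        vs = means.vs
    if not (bg.vs is means.vs or bg.vs == means.vs):
        raise ValueError("backgrounds embedded under a different visual system")
    rows = []
    for (taxon, sex, patch), row in means.table.iterrows():
        xyz = np.array([row["x"], row["y"], row["z"]])
        cg = float(np.linalg.norm(xyz - bg.green_xyz))
        cb = float(np.linalg.norm(xyz - bg.brown_xyz))
        refl = means.mean_spectra[(taxon, sex, patch)]
        rows.append({
            "taxon_id": taxon, "sex": sex, "patch": patch,
            "contrast_green": cg,
            "contrast_brown": cb,
            "contrast_achro": (
                abs(row["f_d"] - bg.green_catch.f_d) / vs.omega_d
                + abs(row["f_d"] - bg.brown_catch.f_d) / vs.omega_d
            ) / 2.0,
            "conspicuousness": (cg + cb) / 2.0,
            "structural": classify_structural(vs.wavelengths, refl, structural_threshold),
            "n_individuals": int(row["n_individuals"]),
        })
    return pd.DataFrame(rows)


def percent_structural(flags: dict, weights: dict | None = None) -> float:
    """Percent of the body bearing structural colouration.

    ``flags`` maps measured regions to booleans; unmeasured regions count
    as non-structural (with a warning).  ``weights`` are per-region body
    fractions summing to 1 (default: equal, 1/7 each).
    """
    if weights is None:
        weights = {p: 1.0 / len(PATCHES) for p in PATCHES}
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-8:
        raise ValueError(f"region weights sum to {total}, expected 1")
    missing = [p for p in weights if p not in flags]
    if missing:
        logger.warning("regions %s unmeasured; counted as non-structural", missing)
    return 100.0 * sum(w for p, w in weights.items() if flags.get(p, False))
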