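"""Reflectance spectra: reading, validation, cleaning and down-sampling.

Spectra are plumage reflectance measurements over the bird-visible range
(300-700 nm), expressed in percent relative to a white standard.  Each
measurement carries metadata identifying the taxon, sex, individual
specimen, body patch and replicate.  Museum-specimen spectra routinely dip
slightly below zero from instrument noise; negative readings are clamped
to zero on load and the clamp is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The seven body regions measured per specimen.
PATCHES = ("head", "back", "breast", "belly", "cheek", "throat", "tail")

#: Target wavelength grid after down-sampling: 300, 305, ..., 700 nm.
GRID_5NM = np.arange(300.0, 700.0 + 2.5, 5.0)

_SEX_ALIASES = {
    "f": "F", "female": "F", "fem": "F",
    "m": "M", "male": "M",
}


@dataclass(frozen=True)
class SpectrumMeta:
    """Measurement metadata for one reflectance spectrum."""

    measurement_id: str
    taxon_id: str
    sex: str
    individual_id: str
    patch: str
    replicate: int = 1


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """One reflectance measurement on a strictly increasing wavelength grid."""

    wavelengths: np.ndarray
    reflectance: np.ndarray
    meta: SpectrumMeta | None = None

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        r = np.asarray(self.reflectance, dtype=float)
        if wl.ndim != 1 or wl.shape != r.shape:
            raise ValueError("wavelengths and reflectance must be 1-D and equal length")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(r)):
            raise ValueError("reflectance contains non-finite values")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", r)

    @property
    def on_5nm_grid(self) -> bool:
        return self.wavelengths.shape == GRID_5NM.shape and np.allclose(
            self.wavelengths, GRID_5NM
        )


def normalize_sex(value: str) -> str:
    v = str(value).strip()
    if v in ("F", "M"):
        return v
    key = v.lower()
    if key in _SEX_ALIASES:
        return _SEX_ALIASES[key]
    raise ValueError(f"sex {value!r} not in closed vocabulary {{F, M}}")


def normalize_patch(value: str) -> str:
    v = str(value).strip().lower()
    if v not in PATCHES:
        raise ValueError(f"patch {value!r} not one of {PATCHES}")
    return v


class SpectrumCollection:
    """Reflectance spectra indexed by (taxon, sex, individual, patch).

    One to two replicates per (individual, patch) is the expected range;
    more are accepted with a warning.  Missing patches are permitted
    (damaged plumage is simply not measured).
    """

    def __init__(self, spectra: list[ReflectanceSpectrum]):
        self.spectra = list(spectra)
        self._index: dict[tuple, list[ReflectanceSpectrum]] = {}
        for s in self.spectra:
            if s.meta is None:
                raise ValueError("collection spectra require metadata")
            key = (s.meta.taxon_id, s.meta.sex, s.meta.individual_id, s.meta.patch)
            self._index.setdefault(key, []).append(s)
        for key, reps in self._index.items():
            if len(reps) > 2:
                logger.warning(
                    "%d replicates for %s (1-2 expected)", len(reps), key
                )

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def replicates(self, taxon: str, sex: str, individual: str, patch: str):
        return self._index.get((taxon, sex, individual, patch), [])

    def keys(self):
        return sorted(self._index)

    @property
    def taxa(self) -> list[str]:
        return sorted({s.meta.taxon_id for s in self.spectra})


def read_spectra(path, meta_path) -> SpectrumCollection:
    """Read a spectra table and its metadata table into a collection.

    The spectra table is delimited text whose first column is wavelength in
    nm ("wl") and whose remaining columns are measurement IDs; this is the
    de-facto spectrometer export layout.  The metadata table has columns
    measurement_id, taxon_id, sex, individual_id, patch, replicate.
    Columns without a metadata row (and metadata rows without a column)
    are reported and dropped; negative reflectance is clamped to zero.
    """
    raw_header = pd.read_csv(path, sep=None, engine="python", header=None, nrows=1)
    raw_cols = [str(c) for c in raw_header.iloc[0, 1:]]
    if len(set(raw_cols)) != len(raw_cols):
        dupes = sorted({c for c in raw_cols if raw_cols.count(c) > 1})
        raise ValueError(f"{path}: duplicated measurement IDs {dupes}")
    tab = pd.read_csv(path, sep=None, engine="python")
    meta = pd.read_csv(meta_path, sep=None, engine="python", dtype=str)

    wl = tab.iloc[:, 0].to_numpy(dtype=float)
    if not np.all(np.diff(wl) > 0):
        raise ValueError(f"{path}: wavelength column is not strictly increasing")

    sample_cols = list(tab.columns[1:])
    mids = meta["measurement_id"].tolist()
    if len(set(mids)) != len(mids):
        dupes = sorted({m for m in mids if mids.count(m) > 1})
        raise ValueError(f"{meta_path}: duplicated measurement IDs {dupes}")

    meta = meta.set_index("measurement_id")
    unmatched_cols = [c for c in sample_cols if c not in meta.index]
    unmatched_rows = [m for m in meta.index if m not in set(sample_cols)]
    if unmatched_cols:
        logger.warning("dropping %d spectra columns without metadata: %s",
                       len(unmatched_cols), unmatched_cols)
    if unmatched_rows:
        logger.warning("dropping %d metadata rows without spectra: %s",
                       len(unmatched_rows), unmatched_rows)

    spectra = []
    for col in sample_cols:
        if col in unmatched_cols:
            continue
        row = meta.loc[col]
        r = tab[col].to_numpy(dtype=float)
        n_neg = int((r < 0).sum())
        if n_neg:
            logger.warning("%s: clamped %d negative reading(s) to 0", col, n_neg)
            r = np.clip(r, 0.0, None)
        m = SpectrumMeta(
            measurement_id=col,
            taxon_id=str(row["taxon_id"]),
            sex=normalize_sex(row["sex"]),
            individual_id=str(row["individual_id"]),
            patch=normalize_patch(row["patch"]),
            replicate=int(row.get("replicate", 1) or 1),
        )
        spectra.append(ReflectanceSpectrum(wl, r, m))
    return SpectrumCollection(spectra)


def write_spectra(collection_or_pairs, path) -> None:
    """Write spectra in the wl-first-column table layout read by read_spectra."""
    if isinstance(collection_or_pairs, SpectrumCollection):
        pairs = [(s.meta.measurement_id, s) for s in collection_or_pairs]
    else:
        pairs = list(collection_or_pairs)
    wl = pairs[0][1].wavelengths
    data = {"wl": wl}
    for mid, s in pairs:
        if s.wavelengths.shape != wl.shape or not np.allclose(s.wavelengths, wl):
            raise ValueError("all spectra in one table must share a grid")
        data[mid] = s.reflectance
    pd.DataFrame(data).to_csv(path, index=False)


def downsample_5nm(s: ReflectanceSpectrum) -> ReflectanceSpectrum:
    """Down-sample a spectrum to the 81-point 5-nm grid (300, 305, ..., 700).

    Each output value is the mean of input values whose wavelength falls in
    the centered half-open bin [w - 2.5, w + 2.5); edge bins are truncated
    to the data range.  Idempotent for input already on the target grid.
    """
    wl, r = s.wavelengths, s.reflectance
    if wl[0] > 300.0 + 1e-9 or wl[-1] < 700.0 - 1e-9:
        raise ValueError(
            f"input grid [{wl[0]}, {wl[-1]}] does not cover [300, 700]; "
            f"missing {'[300, %g)' % wl[0] if wl[0] > 300 else ''}"
            f"{' and ' if wl[0] > 300 and wl[-1] < 700 else ''}"
            f"{'(%g, 700]' % wl[-1] if wl[-1] < 700 else ''}"
        )
    edges = np.arange(297.5, 702.5 + 2.5, 5.0)  # 82 edges -> 81 bins
    idx = np.searchsorted(edges, wl, side="right") - 1
    keep = (idx >= 0) & (idx < GRID_5NM.size)
    sums = np.bincount(idx[keep], weights=r[keep], minlength=GRID_5NM.size)
    counts = np.bincount(idx[keep], minlength=GRID_5NM.size)
    if np.any(counts == 0):
        gaps = GRID_5NM[counts == 0]
        raise ValueError(f"no input samples in 5-nm bin(s) centered at {gaps} nm")
    return ReflectanceSpectrum(GRID_5NM.copy(), sums / counts, s.meta)
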