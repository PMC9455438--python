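"""Spectral matrices with sample metadata: the shared data model of the pipeline.

A :class:`SpectraSet` holds an ``n x p`` intensity matrix on a common,
strictly increasing energy axis (keV) together with per-sample metadata
(species and geographic origin, the class label).  Raw spectra are
non-negative counts; derivative-processed spectra may be negative and are
marked with ``processed=True``.

On-disk format is plain delimited text (tab by default):

* spectra matrix — row 1 is ``sample_id`` followed by the p channel
  energies; each following row is a sample id followed by p intensities;
* metadata — columns ``sample_id``, ``species``, ``origin``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["SpectraSet", "SpectraError", "read_spectra", "write_spectra"]

META_COLUMNS = ("species", "origin")


class SpectraError(ValueError):
    """Raised when a spectral dataset violates its structural contract."""


@dataclass
class SpectraSet:
    """Labeled collection of spectra on a common channel/energy axis.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, in acquisition order.  Order is
        significant (it fixes cross-validation fold indexing) and is never
        silently sorted.
    channel_energies
        Strictly increasing energy values in keV, length ``p``.
    intensities
        ``n x p`` matrix of counts (raw) or reals (processed).
    meta
        DataFrame indexed by sample id with columns ``species`` and
        ``origin``; ``origin`` is the class label used downstream.
    processed
        False for raw spectra (must be non-negative), True after a
        derivative transform.
    """

    sample_ids: list[str]
    channel_energies: np.ndarray
    intensities: np.ndarray
    meta: pd.DataFrame
    processed: bool = False

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.channel_energies = np.asarray(self.channel_energies, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.validate()

    # -- structural contract -------------------------------------------------

    def validate(self) -> None:
        n, ids = len(self.intensities), self.sample_ids
        if len(ids) != n:
            raise SpectraError(
                f"{len(ids)} sample ids for {n} spectra rows"
            )
        if len(set(ids)) != len(ids):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise SpectraError(f"duplicate sample ids: {dupes}")
        if self.intensities.ndim != 2:
            raise SpectraError("intensities must be a 2-D matrix")
        if self.intensities.shape[1] != self.channel_energies.size:
            raise SpectraError(
                f"{self.intensities.shape[1]} intensity columns but "
                f"{self.channel_energies.size} channel energies"
            )
        if np.any(np.diff(self.channel_energies) <= 0):
            raise SpectraError("channel energies must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise SpectraError("non-finite intensity values")
        if not self.processed and np.any(self.intensities < 0):
            raise SpectraError("raw intensities must be non-negative")
        missing = [s for s in ids if s not in self.meta.index]
        if missing:
            raise SpectraError(f"samples missing from metadata: {missing}")
        for col in META_COLUMNS:
            if col not in self.meta.columns:
                raise SpectraError(f"metadata lacks required column {col!r}")
        # align metadata to sample order; keeps .origins positional
        self.meta = self.meta.loc[ids, list(META_COLUMNS)].copy()

    # -- convenience accessors ----------------------------------------------

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def p(self) -> int:
        return int(self.channel_energies.size)

    @property
    def origins(self) -> np.ndarray:
        """Per-sample class labels, in sample order."""
        return self.meta["origin"].to_numpy()

    @property
    def class_labels(self) -> list[str]:
        """Distinct origin labels, lexicographic."""
        return sorted(self.meta["origin"].unique())

    def subset(self, mask: np.ndarray) -> "SpectraSet":
        """Row-subset by boolean mask or integer index; channel axis unchanged."""
        idx = np.arange(self.n)[mask]
        ids = [self.sample_ids[i] for i in idx]
        return SpectraSet(
            sample_ids=ids,
            channel_energies=self.channel_energies,
            intensities=self.intensities[idx],
            meta=self.meta.loc[ids],
            processed=self.processed,
        )

    def select_species(self, species: str) -> "SpectraSet":
        return self.subset(self.meta["species"].to_numpy() == species)

    def select_origin(self, origin: str) -> "SpectraSet":
        return self.subset(self.origins == origin)

    def with_intensities(self, values: np.ndarray, processed: bool) -> "SpectraSet":
        return replace(self, intensities=np.asarray(values, float), processed=processed)


def read_spectra(matrix_path, meta_path, sep: str = "\t") -> SpectraSet:
    """Read a spectra matrix / metadata file pair.

    The matrix header row carries the channel energies; the first column the
    sample ids.  Metadata is joined by ``sample_id``; every sample in the
    matrix must be present.  Row order of the matrix is preserved.
    """
    mat = pd.read_csv(matrix_path, sep=sep, header=0, dtype=str)
    if mat.shape[1] < 2:
        raise SpectraError(f"{matrix_path}: expected sample_id column plus channels")
    sample_ids = mat.iloc[:, 0].astype(str).tolist()
    try:
        energies = np.array([float(c) for c in mat.columns[1:]])
    except ValueError as exc:
        raise SpectraError(f"{matrix_path}: non-numeric energy header: {exc}") from exc
    try:
        intensities = mat.iloc[:, 1:].to_numpy(dtype=float)
    except ValueError as exc:
        raise SpectraError(f"{matrix_path}: non-numeric intensity value: {exc}") from exc

    meta = pd.read_csv(meta_path, sep=sep, dtype=str)
    required = {"sample_id", *META_COLUMNS}
    if not required.issubset(meta.columns):
        raise SpectraError(
            f"{meta_path}: metadata needs columns {sorted(required)}, "
            f"found {list(meta.columns)}"
        )
    meta = meta.set_index("sample_id")

    processed = bool(np.any(intensities < 0))
    return SpectraSet(
        sample_ids=sample_ids,
        channel_energies=energies,
        intensities=intensities,
        meta=meta,
        processed=processed,
    )


def write_spectra(s: SpectraSet, matrix_path, meta_path, sep: str = "\t") -> None:
    """Write the TSV pair read back by :func:`read_spectra`.

    Values are written with 17 significant digits so a round trip preserves
    float64 exactly.
    """
    if s.n == 0:
        raise SpectraError("refusing to write an empty SpectraSet")
    header = ["sample_id"] + [format(e, ".17g") for e in s.channel_energies]
    with open(matrix_path, "w") as fh:
        fh.write(sep.join(header) + "\n")
        for sid, row in zip(s.sample_ids, s.intensities):
            fh.write(sid + sep + sep.join(format(v, ".17g") for v in row) + "\n")
    s.meta.reset_index(names="sample_id").to_csv(meta_path, sep=sep, index=False)
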