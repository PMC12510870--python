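"""Per-particle conformational landscapes and their file formats.

A *landscape* is the per-particle latent embedding produced by a
heterogeneity-analysis method: one row per particle image, one column per
latent dimension.  Several landscapes estimated from the *same* ordered set
of particle images form a :class:`LandscapeSet`, the input of the consensus
network.  Landscapes are exchanged as delimited text (CSV/TSV, optional
``id`` column) or as NPY arrays with a plain-text id sidecar.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Landscape",
    "LandscapeSet",
    "LandscapeError",
    "AlignmentError",
    "read_landscape",
    "write_landscape",
    "pair_landscapes",
]


class LandscapeError(ValueError):
    """Raised for malformed landscape files or invalid landscape data."""


class AlignmentError(LandscapeError):
    """Raised when landscapes cannot be paired over a common particle set."""


@dataclass(frozen=True)
class Landscape:
    """One method's latent matrix plus particle identifiers.

    Parameters
    ----------
    label
        Free-text name of the method/run that produced the embedding.
    ids
        Ordered particle identifiers, one per row of ``X``.
    X
        Real matrix of shape ``(num_particles, dim)``.
    """

    label: str
    ids: tuple
    X: np.ndarray

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2:
            raise LandscapeError(f"landscape {self.label!r}: X must be 2-D, got ndim={X.ndim}")
        if X.shape[0] == 0:
            raise LandscapeError(f"landscape {self.label!r}: empty landscape (no particles)")
        if X.shape[1] == 0:
            raise LandscapeError(f"landscape {self.label!r}: no coordinate columns")
        if not np.all(np.isfinite(X)):
            bad = np.argwhere(~np.isfinite(X))[0]
            raise LandscapeError(
                f"landscape {self.label!r}: non-finite coordinate at row {bad[0]}, column {bad[1]}"
            )
        ids = tuple(self.ids)
        if len(ids) != X.shape[0]:
            raise LandscapeError(
                f"landscape {self.label!r}: {len(ids)} ids for {X.shape[0]} rows"
            )
        if len(set(ids)) != len(ids):
            raise LandscapeError(f"landscape {self.label!r}: duplicate particle ids")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "X", X)

    @property
    def num_particles(self) -> int:
        return self.X.shape[0]

    @property
    def dim(self) -> int:
        return self.X.shape[1]

    def reorder(self, new_ids: Sequence) -> "Landscape":
        """Return a copy with rows permuted into the order of ``new_ids``."""
        pos = {pid: k for k, pid in enumerate(self.ids)}
        try:
            idx = np.array([pos[pid] for pid in new_ids], dtype=int)
        except KeyError as exc:
            raise AlignmentError(
                f"landscape {self.label!r} has no particle {exc.args[0]!r}"
            ) from None
        return Landscape(self.label, tuple(new_ids), self.X[idx])


@dataclass(frozen=True)
class LandscapeSet:
    """N >= 2 landscapes over the identical ordered particle list.

    Dimensions may differ between landscapes; ids and their order may not.
    """

    landscapes: tuple = field(default_factory=tuple)

    def __post_init__(self):
        ls = tuple(self.landscapes)
        if len(ls) < 2:
            raise LandscapeError(f"a LandscapeSet needs at least 2 landscapes, got {len(ls)}")
        ref = ls[0].ids
        for l in ls[1:]:
            if l.ids != ref:
                raise AlignmentError(
                    f"landscape {l.label!r} is not aligned with {ls[0].label!r}; "
                    "use pair_landscapes() first"
                )
        object.__setattr__(self, "landscapes", ls)

    @property
    def N(self) -> int:
        return len(self.landscapes)

    @property
    def ids(self) -> tuple:
        return self.landscapes[0].ids

    @property
    def num_particles(self) -> int:
        return self.landscapes[0].num_particles

    @property
    def dims(self) -> tuple:
        return tuple(l.dim for l in self.landscapes)

    @property
    def labels(self) -> tuple:
        return tuple(l.label for l in self.landscapes)

    def matrices(self) -> list:
        return [l.X for l in self.landscapes]

    def __iter__(self):
        return iter(self.landscapes)

    def __len__(self) -> int:
        return len(self.landscapes)


_TEXT_FORMATS = {"csv": ",", "tsv": "\t"}


def _coerce_id(value):
    """Integer-looking ids stay integers so write/read round-trips exactly."""
    s = str(value).strip()
    try:
        return int(s)
    except ValueError:
        return s


def _read_delimited(path: Path, sep: str, label: str) -> Landscape:
    try:
        raw = path.read_text()
    except UnicodeDecodeError:
        raise LandscapeError(f"{path}: not a text file (wrong format?)") from None
    if not raw.strip():
        raise LandscapeError(f"{path}: empty file")
    first = raw.splitlines()[0]
    # a header is any first line with a non-numeric field
    has_header = False
    for tok in first.split(sep):
        try:
            float(tok)
        except ValueError:
            has_header = True
            break
    try:
        df = pd.read_csv(io.StringIO(raw), sep=sep, header=0 if has_header else None,
                         float_precision="round_trip")
    except Exception as exc:
        raise LandscapeError(f"{path}: cannot parse as delimited text ({exc})") from None
    id_col = None
    if has_header:
        for c in df.columns:
            if str(c).strip().lower() == "id":
                id_col = c
                break
    if id_col is not None:
        ids = tuple(_coerce_id(v) for v in df[id_col])
        data = df.drop(columns=[id_col])
    else:
        ids = tuple(range(len(df)))
        data = df
    for c in data.columns:
        col = pd.to_numeric(data[c], errors="coerce")
        if col.isna().any() and not data[c].isna().any():
            row = int(col.isna().idxmax())
            raise LandscapeError(
                f"{path}: non-numeric value {data[c][row]!r} at row {row}, column {c!r}"
            )
        data[c] = col
    X = data.to_numpy(dtype=float)
    return Landscape(label, ids, X)


def read_landscape(path, format: str | None = None, label: str | None = None) -> Landscape:
    """Read a landscape from ``path``.

    ``format`` is one of ``csv``, ``tsv`` or ``npy``; when omitted it is
    inferred from the file suffix.  NPY arrays may have a sidecar
    ``<stem>.ids.txt`` with one particle id per line; text formats may carry
    an ``id`` column.  Without either, ids default to ``0..n-1``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".npy": "npy"}.get(path.suffix.lower())
        if format is None:
            raise LandscapeError(f"{path}: cannot infer format from suffix; pass format=")
    label = label if label is not None else path.stem
    if format in _TEXT_FORMATS:
        return _read_delimited(path, _TEXT_FORMATS[format], label)
    if format == "npy":
        try:
            X = np.load(path, allow_pickle=False)
        except ValueError as exc:
            raise LandscapeError(f"{path}: not a valid NPY array file ({exc})") from None
        sidecar = path.with_suffix(".ids.txt")
        if sidecar.exists():
            ids = tuple(_coerce_id(v) for v in sidecar.read_text().split())
        else:
            ids = tuple(range(X.shape[0]))
        return Landscape(label, ids, X)
    raise LandscapeError(f"unknown landscape format {format!r}")


def write_landscape(landscape: Landscape, path, format: str | None = None) -> None:
    """Write ``landscape`` to ``path`` (csv/tsv with an id column, or npy + id sidecar)."""
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".npy": "npy"}.get(path.suffix.lower())
        if format is None:
            raise LandscapeError(f"{path}: cannot infer format from suffix; pass format=")
    path.parent.mkdir(parents=True, exist_ok=True)
    if format in _TEXT_FORMATS:
        sep = _TEXT_FORMATS[format]
        cols = [f"z{k + 1}" for k in range(landscape.dim)]
        df = pd.DataFrame(landscape.X, columns=cols)
        df.insert(0, "id", list(landscape.ids))
        df.to_csv(path, sep=sep, index=False, float_format="%.17g")
    elif format == "npy":
        np.save(path, landscape.X)
        sidecar = path.with_suffix(".ids.txt")
        sidecar.write_text("\n".join(str(i) for i in landscape.ids) + "\n")
    else:
        raise LandscapeError(f"unknown landscape format {format!r}")


def pair_landscapes(landscapes: Sequence[Landscape]) -> LandscapeSet:
    """Align N >= 2 landscapes over a common particle set.

    Row order follows the first landscape; landscapes whose ids are the same
    set in a different order are re-ordered.  Unequal id sets raise
    :class:`AlignmentError` naming the unmatched ids on each side.
    """
    ls = list(landscapes)
    if len(ls) < 2:
        raise LandscapeError(f"need at least 2 landscapes to pair, got {len(ls)}")
    ref = ls[0]
    ref_set = set(ref.ids)
    aligned = [ref]
    for l in ls[1:]:
        if l.ids == ref.ids:
            aligned.append(l)
            continue
        other = set(l.ids)
        if other != ref_set:
            missing_here = sorted(map(str, ref_set - other))
            missing_ref = sorted(map(str, other - ref_set))
            raise AlignmentError(
                f"landscape {l.label!r} does not cover the same particles as {ref.label!r}: "
                f"missing {missing_here[:10]}, extra {missing_ref[:10]}"
            )
        aligned.append(l.reorder(ref.ids))
    return LandscapeSet(tuple(aligned))
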