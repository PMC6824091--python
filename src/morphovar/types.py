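"""Core data model for 3D landmark samples and landmark partitions.

Landmark indices are 0-based everywhere inside the library; every file
format and every report uses the 1-based convention of the morphometrics
literature. Conversions happen exclusively at the I/O boundary
(:mod:`morphovar.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["Configuration", "Sample", "Partition", "MorphovarError", "StructuralError"]


class MorphovarError(ValueError):
    """Base class for all validation and parse errors raised by this package."""


class StructuralError(MorphovarError):
    """Input violates a structural requirement (landmark counts, duplicates...)."""


@dataclass
class Configuration:
    """One specimen's ordered 3D landmark coordinates.

    Parameters
    ----------
    specimen_id:
        Free-text identifier, unique within a :class:`Sample`.
    coords:
        ``(L, 3)`` float array; units are arbitrary but consistent and become
        dimensionless after Procrustes scaling.
    landmark_ids:
        Optional ordered labels, defaulting to ``"1" .. "L"``.
    """

    specimen_id: str
    coords: np.ndarray
    landmark_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise StructuralError(
                f"specimen {self.specimen_id!r}: coords must be (L, 3), "
                f"got {self.coords.shape}"
            )
        if self.coords.shape[0] < 4:
            raise StructuralError(
                f"specimen {self.specimen_id!r}: at least 4 landmarks are required "
                f"for 3D analyses, got {self.coords.shape[0]}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise StructuralError(
                f"specimen {self.specimen_id!r}: non-finite coordinate"
            )
        if self.landmark_ids is None:
            self.landmark_ids = [str(i + 1) for i in range(self.n_landmarks)]
        else:
            self.landmark_ids = [str(l) for l in self.landmark_ids]
            if len(self.landmark_ids) != self.n_landmarks:
                raise StructuralError(
                    f"specimen {self.specimen_id!r}: {len(self.landmark_ids)} "
                    f"landmark ids for {self.n_landmarks} landmarks"
                )
            if len(set(self.landmark_ids)) != len(self.landmark_ids):
                raise StructuralError(
                    f"specimen {self.specimen_id!r}: duplicate landmark ids"
                )

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "Configuration":
        return Configuration(self.specimen_id, self.coords.copy(), list(self.landmark_ids))


@dataclass
class Sample:
    """An ordered collection of configurations plus per-specimen metadata.

    All configurations must share the landmark count; specimen ids must be
    unique; ``metadata`` rows correspond 1:1 (positionally) to configurations.
    """

    configurations: list[Configuration]
    metadata: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.configurations:
            raise StructuralError("a Sample needs at least one configuration")
        L = self.configurations[0].n_landmarks
        for c in self.configurations:
            if c.n_landmarks != L:
                raise StructuralError(
                    f"specimen {c.specimen_id!r} has {c.n_landmarks} landmarks, "
                    f"expected {L}"
                )
        ids = [c.specimen_id for c in self.configurations]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise StructuralError(f"duplicate specimen ids: {dup}")
        if self.metadata is None:
            self.metadata = pd.DataFrame(index=pd.Index(ids, name="specimen"))
        else:
            if len(self.metadata) != len(ids):
                raise StructuralError(
                    f"metadata has {len(self.metadata)} rows for "
                    f"{len(ids)} configurations"
                )
            self.metadata = self.metadata.copy()
            self.metadata.index = pd.Index(ids, name="specimen")

    @property
    def n_specimens(self) -> int:
        return len(self.configurations)

    @property
    def n_landmarks(self) -> int:
        return self.configurations[0].n_landmarks

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    @property
    def landmark_ids(self) -> list[str]:
        return list(self.configurations[0].landmark_ids)

    @property
    def coords(self) -> np.ndarray:
        """``(n, L, 3)`` stacked coordinates."""
        return np.stack([c.coords for c in self.configurations])


@dataclass(eq=False)  # identity hash so partitions can key mappings
class Partition:
    """A named subset of landmark indices (a morphological hypothesis region).

    ``indices`` are 0-based, unique and sorted on construction.
    """

    name: str
    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices)
        if idx.size == 0:
            raise StructuralError(f"partition {self.name!r}: empty index list")
        if idx.dtype.kind not in "iu" and not np.all(idx == idx.astype(int)):
            raise StructuralError(f"partition {self.name!r}: non-integer index")
        idx = idx.astype(int)
        if np.any(idx < 0):
            raise StructuralError(f"partition {self.name!r}: negative index")
        if len(np.unique(idx)) != idx.size:
            raise StructuralError(f"partition {self.name!r}: duplicate indices")
        self.indices = np.sort(idx)

    def __len__(self) -> int:
        return int(self.indices.size)

    def validate_against(self, n_landmarks: int) -> None:
        if int(self.indices.max()) >= n_landmarks:
            raise StructuralError(
                f"partition {self.name!r}: index {int(self.indices.max()) + 1} "
                f"(1-based) exceeds landmark count {n_landmarks}"
            )

    def complement(self, n_landmarks: int, name: str = "remainder") -> "Partition":
        self.validate_against(n_landmarks)
        mask = np.ones(n_landmarks, dtype=bool)
        mask[self.indices] = False
        if not mask.any():
            raise StructuralError(
                f"partition {self.name!r} covers all landmarks; empty complement"
            )
        return Partition(name, np.flatnonzero(mask))


def remainder_partition(
    partitions: Iterable[Partition], n_landmarks: int, name: str = "remainder"
) -> Partition | None:
    """Complement of the union of ``partitions``; None if nothing remains."""
    mask = np.ones(n_landmarks, dtype=bool)
    for p in partitions:
        p.validate_against(n_landmarks)
        mask[p.indices] = False
    if not mask.any():
        return None
    return Partition(name, np.flatnonzero(mask))
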