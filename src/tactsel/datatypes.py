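"""Shared in-memory containers: genotype tables, pedigrees, landmark sets."""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import MISSING


@dataclass
class Pedigree:
    """Known maternity plus ground-truth paternity for simulated offspring.

    ``links`` has one row per offspring with columns offspring_id, dam_id,
    sire_id.  ``male_ids`` / ``dam_ids`` list the founder adults.
    """

    male_ids: list[str]
    dam_ids: list[str]
    links: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"offspring_id", "dam_id", "sire_id"}
        if not required.issubset(self.links.columns):
            raise ValueError(f"pedigree links need columns {sorted(required)}")

    @property
    def offspring_ids(self) -> list[str]:
        return list(self.links["offspring_id"])


@dataclass
class GenotypeTable:
    """Diploid multi-locus calls for dams, candidate sires and offspring.

    Calls are stored per locus as an (n, 2) integer array of allele fragment
    sizes (bp), sorted within each pair; missing alleles use the sentinel
    ``MISSING`` (-1).  ``dam_id`` links each offspring to its known mother.
    """

    ids: list[str]
    roles: list[str]  # dam | sire | offspring
    dam_ids: list[str | None]
    calls: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        n = len(self.ids)
        if not (len(self.roles) == len(self.dam_ids) == n):
            raise ValueError("ids, roles, dam_ids must have equal length")
        bad = set(self.roles) - {"dam", "sire", "offspring"}
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")
        for locus, arr in self.calls.items():
            arr = np.asarray(arr, dtype=int)
            if arr.shape != (n, 2):
                raise ValueError(f"{locus}: calls must be (n, 2)")
            # order alleles within each pair; missing (-1) sorts first
            self.calls[locus] = np.sort(arr, axis=1)
        self._index = {i: k for k, i in enumerate(self.ids)}

    @property
    def loci(self) -> list[str]:
        return list(self.calls)

    def __len__(self) -> int:
        return len(self.ids)

    def row(self, individual_id: str) -> int:
        return self._index[individual_id]

    def genotype(self, individual_id: str, locus: str) -> np.ndarray:
        return self.calls[locus][self._index[individual_id]]

    def subset(self, mask: np.ndarray) -> "GenotypeTable":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeTable(
            ids=[i for i, m in zip(self.ids, mask) if m],
            roles=[r for r, m in zip(self.roles, mask) if m],
            dam_ids=[d for d, m in zip(self.dam_ids, mask) if m],
            calls={loc: arr[mask] for loc, arr in self.calls.items()},
        )

    def by_role(self, role: str) -> "GenotypeTable":
        return self.subset(np.array([r == role for r in self.roles]))

    def to_frame(self) -> pd.DataFrame:
        """CSV-facing frame: id, role, dam_id, then one 'a1/a2' column per
        locus with missing alleles written as NA."""
        def fmt(a: int) -> str:
            return "NA" if a == MISSING else str(a)

        data = {
            "id": self.ids,
            "role": self.roles,
            "dam_id": ["" if d is None else d for d in self.dam_ids],
        }
        for locus, arr in self.calls.items():
            data[locus] = [f"{fmt(a)}/{fmt(b)}" for a, b in arr]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GenotypeTable":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        meta = {"id", "role", "dam_id"}
        loci = [c for c in df.columns if c not in meta]
        calls = {}
        for locus in loci:
            pairs = np.full((len(df), 2), MISSING, dtype=int)
            for k, cell in enumerate(df[locus]):
                a, _, b = str(cell).partition("/")
                for j, tok in enumerate((a, b)):
                    tok = tok.strip()
                    if tok and tok.upper() != "NA":
                        pairs[k, j] = int(tok)
            calls[locus] = pairs
        return cls(
            ids=list(df["id"]),
            roles=list(df["role"]),
            dam_ids=[d if d else None for d in df.get("dam_id", [""] * len(df))],
            calls=calls,
        )


@dataclass
class LandmarkSet:
    """Per-individual 2-D landmark configurations with slider definitions.

    ``coords`` is (n, k, 2) in image units; missing landmarks are NaN.
    ``sliders`` are 0-based (before, slider, after) index triples.
    """

    ids: list[str]
    coords: np.ndarray
    sliders: tuple[tuple[int, int, int], ...] = ()

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValueError("coords must be (n, k, 2)")
        if self.coords.shape[0] != len(self.ids):
            raise ValueError("ids and coords disagree on n")
        if self.coords.shape[1] < 3:
            raise ValueError("need at least 3 landmarks (shape undefined below k=3)")
        k = self.coords.shape[1]
        for b, s, a in self.sliders:
            if len({b, s, a}) != 3 or not all(0 <= j < k for j in (b, s, a)):
                raise ValueError(f"invalid slider triple {(b, s, a)}")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    @property
    def missing(self) -> np.ndarray:
        """(n, k) boolean mask of missing landmarks."""
        return np.isnan(self.coords).any(axis=2)


def write_tps(path, landmarks: LandmarkSet, scale: float | None = None) -> None:
    """Write the tpsDig dialect: LM=k, k coordinate lines, ID= record (and
    SCALE= when given)."""
    with open(path, "w") as fh:
        for i in range(landmarks.n):
            fh.write(f"LM={landmarks.k}\n")
            for x, y in landmarks.coords[i]:
                fh.write(f"{x:.6f} {y:.6f}\n")
            if scale is not None:
                fh.write(f"SCALE={scale:.6f}\n")
            fh.write(f"ID={landmarks.ids[i]}\n")


def read_tps(
    path,
    sliders: tuple[tuple[int, int, int], ...] = (),
    flip_y: bool = False,
) -> LandmarkSet:
    """Read a TPS landmark file (LM=, coordinate pairs, ID=/IMAGE=/SCALE=).

    The SCALE= factor, when present, multiplies that specimen's coordinates.
    ``flip_y`` negates the y axis, for files digitized in image coordinates
    where y grows downward.
    """
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    specimens: list[np.ndarray] = []
    ids: list[str] = []
    current: list[list[float]] | None = None
    expect = 0
    scale = None

    def close_specimen():
        nonlocal current, scale
        if current is None:
            return
        arr = np.asarray(current, dtype=float)
        if len(arr) != expect:
            raise ValueError(
                f"TPS record {len(specimens) + 1}: LM={expect} but "
                f"{len(arr)} coordinate lines"
            )
        if scale is not None:
            arr = arr * scale
        specimens.append(arr)
        if len(ids) < len(specimens):
            ids.append(f"specimen_{len(specimens)}")
        current, scale = None, None

    for raw in lines:
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM="):
            close_specimen()
            expect = int(line.split("=", 1)[1])
            current = []
        elif upper.startswith("ID="):
            ids.append(line.split("=", 1)[1].strip())
        elif upper.startswith("SCALE="):
            scale = float(line.split("=", 1)[1])
        elif upper.startswith(("IMAGE=", "CURVES=", "POINTS=", "COMMENT=")):
            continue
        else:
            if current is None:
                raise ValueError("coordinate line outside an LM= record")
            parts = line.split()
            current.append([float(parts[0]), float(parts[1])])
    close_specimen()
    coords = np.stack(specimens) if specimens else np.empty((0, 0, 2))
    if flip_y:
        coords = coords.copy()
        coords[..., 1] *= -1.0
    return LandmarkSet(ids=ids, coords=coords, sliders=sliders)
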