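"""Volume and record I/O: masking, pad/trim-to-cube, channel stacking, NIfTI
and a framed binary sample-record container.

The data contract throughout the package follows the VBM output convention:
each subject has co-registered gray-matter (GM) and white-matter (WM)
tissue-density grids on a shared voxel lattice, with every in-brain voxel in
``[0, 1]`` and every background voxel set to exactly ``-1`` (the offset from
low-but-positive tissue probabilities makes the background unambiguous to a
learner).  Voxel indices are 0-based in NIfTI ``(i, j, k)`` axis order.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import nibabel as nib
import numpy as np

BACKGROUND = np.float32(-1.0)

#: default voxel-to-world mapping: 1.5 mm isotropic, axis-aligned
DEFAULT_AFFINE = np.diag([1.5, 1.5, 1.5, 1.0])


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class PhenotypeRecord:
    """Subject labels: age in years, binary gender and diagnosis.

    Encoding (the field's datasets leave this implicit, so it is fixed here
    and repeated in every report header): ``gender`` 1 = female, 0 = male;
    ``diagnosis`` 1 = disorder, 0 = healthy control; ``disorder_name``
    tags which disorder the positive class means (e.g. ASD or ADHD).
    """

    subject_id: str
    age: float
    gender: int
    diagnosis: int
    disorder_name: str = "ADHD"

    MAX_PLAUSIBLE_AGE = 25.0

    def __post_init__(self):
        if not 0.0 < self.age <= self.MAX_PLAUSIBLE_AGE:
            raise ValueError(
                f"age {self.age} outside plausible range (0, {self.MAX_PLAUSIBLE_AGE}] "
                f"for subject {self.subject_id}")
        if self.gender not in (0, 1) or self.diagnosis not in (0, 1):
            raise ValueError("gender and diagnosis must be binary (0/1)")

    def to_dict(self) -> dict:
        return {"subject_id": self.subject_id, "age": float(self.age),
                "gender": int(self.gender), "diagnosis": int(self.diagnosis),
                "disorder_name": self.disorder_name}

    @classmethod
    def from_dict(cls, d: dict) -> "PhenotypeRecord":
        return cls(subject_id=str(d["subject_id"]), age=float(d["age"]),
                   gender=int(d["gender"]), diagnosis=int(d["diagnosis"]),
                   disorder_name=str(d.get("disorder_name", "ADHD")))


@dataclass
class TissueVolumePair:
    """One subject's GM and WM density grids on a shared lattice."""

    subject_id: str
    gm: np.ndarray
    wm: np.ndarray

    def __post_init__(self):
        self.gm = np.asarray(self.gm, dtype=np.float32)
        self.wm = np.asarray(self.wm, dtype=np.float32)
        if self.gm.shape != self.wm.shape:
            raise ValueError(f"GM shape {self.gm.shape} != WM shape {self.wm.shape}")
        if self.gm.ndim != 3:
            raise ValueError("tissue grids must be 3-D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.gm.shape

    def brain_mask(self) -> np.ndarray:
        """Voxels not marked as background in either tissue."""
        return (self.gm != BACKGROUND) | (self.wm != BACKGROUND)


@dataclass
class SampleTensor:
    """Channel-last model input ``(X, Y, Z, 2)``: channel 0 GM, channel 1 WM."""

    values: np.ndarray
    phenotype: PhenotypeRecord

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 4 or self.values.shape[-1] != 2:
            raise ValueError("SampleTensor values must be (X, Y, Z, 2)")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.values.shape[:3]


# ---------------------------------------------------------------------------
# preprocessing operations


def apply_background_mask(pair: TissueVolumePair, brain_mask: np.ndarray) -> TissueVolumePair:
    """Set voxels outside ``brain_mask`` to -1 in both tissues.

    In-brain voxels pass through bit-exact; masking is idempotent.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != pair.shape:
        raise ValueError(f"mask shape {brain_mask.shape} != volume shape {pair.shape}")
    gm = np.where(brain_mask, pair.gm, BACKGROUND)
    wm = np.where(brain_mask, pair.wm, BACKGROUND)
    return TissueVolumePair(pair.subject_id, gm, wm)


def cohort_brain_mask(pairs: Iterable[TissueVolumePair]) -> np.ndarray:
    """Default common mask: union over the cohort of voxels with positive
    density in either tissue."""
    mask = None
    for pair in pairs:
        m = (pair.gm > 0) | (pair.wm > 0)
        mask = m if mask is None else (mask | m)
    if mask is None:
        raise ValueError("empty cohort")
    return mask


class DataLossError(ValueError):
    """Trimming would discard voxels that are not background."""


def _pad_trim_axis(extent: int, target: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """Per-axis (pad_before, pad_after), (trim_lo, trim_hi); centred, extra on
    the high side when the difference is odd."""
    if extent < target:
        total = target - extent
        return (total // 2, total - total // 2), (0, 0)
    total = extent - target
    return (0, 0), (total // 2, total - total // 2)


def _pad_to_cube_array(values: np.ndarray, target_edge: int,
                       background: np.ndarray | float) -> np.ndarray:
    """Pad/trim the three leading axes of ``values`` to ``target_edge``."""
    pads, slices = [], []
    for axis in range(3):
        (plo, phi), (tlo, thi) = _pad_trim_axis(values.shape[axis], target_edge)
        extent = values.shape[axis]
        if tlo or thi:
            lo_planes = values.take(range(tlo), axis=axis)
            hi_planes = values.take(range(extent - thi, extent), axis=axis)
            for planes, side in ((lo_planes, "low"), (hi_planes, "high")):
                if planes.size and not np.all(planes == background):
                    raise DataLossError(
                        f"trimming axis {axis} ({side} side) would remove in-brain voxels")
        pads.append((plo, phi))
        slices.append(slice(tlo, extent - thi))
    out = values[tuple(slices)]
    pads += [(0, 0)] * (values.ndim - 3)
    if any(p != (0, 0) for p in pads):
        out = np.pad(out, pads, constant_values=background)
    return out


def pad_to_cube(item: TissueVolumePair | SampleTensor, target_edge: int = 128):
    """Pad and/or trim each spatial axis to ``target_edge`` voxels.

    Padding voxels are background (-1); trimming is only allowed to remove
    all-background planes, otherwise :class:`DataLossError` is raised.  The
    canonical use is taking the 121 x 145 x 121 MNI grid to 128^3.
    """
    if target_edge < 8:
        raise ValueError("target_edge must be >= 8")
    if isinstance(item, TissueVolumePair):
        if item.shape == (target_edge,) * 3:
            return item
        return TissueVolumePair(
            item.subject_id,
            _pad_to_cube_array(item.gm, target_edge, BACKGROUND),
            _pad_to_cube_array(item.wm, target_edge, BACKGROUND))
    if isinstance(item, SampleTensor):
        if item.spatial_shape == (target_edge,) * 3:
            return item
        return SampleTensor(_pad_to_cube_array(item.values, target_edge, BACKGROUND),
                            item.phenotype)
    raise TypeError(f"unsupported type {type(item).__name__}")


def stack_channels(pair: TissueVolumePair, phenotype: PhenotypeRecord) -> SampleTensor:
    """Stack GM/WM into the two-channel model input (values bit-identical)."""
    values = np.stack([pair.gm, pair.wm], axis=-1)
    return SampleTensor(values, phenotype)


def unstack_channels(sample: SampleTensor) -> TissueVolumePair:
    return TissueVolumePair(sample.phenotype.subject_id,
                            sample.values[..., 0], sample.values[..., 1])


# ---------------------------------------------------------------------------
# NIfTI

def write_nifti(values: np.ndarray, path: str | Path,
                affine: np.ndarray = DEFAULT_AFFINE) -> None:
    img = nib.Nifti1Image(np.asarray(values), affine)
    nib.save(img, str(path))


def read_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Returns (data, affine); data dtype is preserved as stored."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


# ---------------------------------------------------------------------------
# serialized sample records
#
# Framed binary container (documented, versioned):
#   file     := magic 'VBMREC' + u16 version (little endian) + record*
#   record   := u32 header_len + header_json + payload (float32, C order)
# The header JSON holds the phenotype dict, the tensor shape and the payload
# byte length, so records can be streamed one at a time.

MAGIC = b"VBMREC"
RECORD_VERSION = 1


class RecordParseError(ValueError):
    pass


def write_records(samples: Iterable[SampleTensor], path: str | Path) -> int:
    """Serialize samples; returns the number of records written."""
    n = 0
    with open(path, "wb") as fh:
        fh.write(MAGIC + struct.pack("<H", RECORD_VERSION))
        for sample in samples:
            values = np.ascontiguousarray(sample.values, dtype=np.float32)
            header = json.dumps({
                "phenotype": sample.phenotype.to_dict(),
                "shape": list(values.shape),
                "nbytes": int(values.nbytes),
            }).encode()
            fh.write(struct.pack("<I", len(header)))
            fh.write(header)
            fh.write(values.tobytes())
            n += 1
    return n


def iter_records(path: str | Path) -> Iterator[SampleTensor]:
    """Stream samples one record at a time (no full-file load)."""
    with open(path, "rb") as fh:
        head = fh.read(8)
        if len(head) < 8 or head[:6] != MAGIC:
            raise RecordParseError(f"{path}: not a vbmnet record file")
        (version,) = struct.unpack("<H", head[6:8])
        if version != RECORD_VERSION:
            raise RecordParseError(f"{path}: unsupported record version {version}")
        index = 0
        while True:
            lenb = fh.read(4)
            if not lenb:
                return
            if len(lenb) < 4:
                raise RecordParseError(f"{path}: record {index} truncated (length prefix)")
            (hlen,) = struct.unpack("<I", lenb)
            header = fh.read(hlen)
            if len(header) < hlen:
                raise RecordParseError(f"{path}: record {index} truncated (header)")
            try:
                meta = json.loads(header)
            except json.JSONDecodeError as exc:
                raise RecordParseError(f"{path}: record {index} has a corrupt header") from exc
            payload = fh.read(meta["nbytes"])
            if len(payload) < meta["nbytes"]:
                raise RecordParseError(f"{path}: record {index} truncated (payload)")
            values = np.frombuffer(payload, dtype=np.float32).reshape(meta["shape"])
            yield SampleTensor(values.copy(), PhenotypeRecord.from_dict(meta["phenotype"]))
            index += 1


def read_records(path: str | Path) -> list[SampleTensor]:
    return list(iter_records(path))


# ---------------------------------------------------------------------------
# phenotype tables


def phenotypes_to_frame(phenotypes: Iterable[PhenotypeRecord]):
    import pandas as pd

    return pd.DataFrame([p.to_dict() for p in phenotypes])


def write_phenotypes_csv(phenotypes: Iterable[PhenotypeRecord], path: str | Path) -> None:
    phenotypes_to_frame(phenotypes).to_csv(path, index=False)


def read_phenotypes_csv(path: str | Path) -> list[PhenotypeRecord]:
    import pandas as pd

    df = pd.read_csv(path)
    return [PhenotypeRecord.from_dict(row) for row in df.to_dict("records")]
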