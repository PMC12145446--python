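"""Dataset index handling, image preprocessing and cross-validation splits.

The on-disk layout is a CSV index (one row per image; header
``sample_id,label,compound,platform,day,z,path``) next to TIFF/PNG frames.
Labels follow the three-level DILI-concern vocabulary; the "Ambiguous
DILI-concern" category is rejected at load time rather than silently mapped,
because its causal evidence is by definition insufficient for a class label.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from .errors import ConfigurationError, LabelingError, ValidationError
from .synthetic_organoid import OrganoidStack

__all__ = [
    "DiliLabel",
    "DatasetIndex",
    "load_index",
    "load_stack",
    "preprocess_image",
    "preprocess_stack",
    "split_kfold",
]


class DiliLabel(enum.Enum):
    """Three-level DILI-concern label with a fixed class-index mapping."""

    NO = "vNo-DILI-Concern"
    LESS = "vLess-DILI-Concern"
    MOST = "vMost-DILI-Concern"

    @property
    def class_index(self) -> int:
        return {"vNo-DILI-Concern": 0, "vLess-DILI-Concern": 1, "vMost-DILI-Concern": 2}[self.value]

    @classmethod
    def from_string(cls, s: str) -> "DiliLabel":
        for member in cls:
            if member.value == s:
                return member
        if "ambiguous" in s.lower():
            raise LabelingError(
                f"label {s!r} belongs to the Ambiguous DILI-concern category, "
                "which is excluded from the three-class task (insufficient causal evidence)"
            )
        raise LabelingError(f"unknown DILI label {s!r}; expected one of "
                            f"{[m.value for m in cls]}")

    @classmethod
    def from_index(cls, i: int) -> "DiliLabel":
        return [cls.NO, cls.LESS, cls.MOST][int(i)]


CLASS_NAMES = tuple(m.value for m in DiliLabel)


@dataclass
class DatasetIndex:
    """Validated view of a dataset index CSV (one row per image)."""

    frame: pd.DataFrame
    base_dir: Path = field(default_factory=Path)

    REQUIRED_COLUMNS = ("sample_id", "label", "compound", "platform", "day", "z", "path")

    def __post_init__(self):
        self.base_dir = Path(self.base_dir)
        missing = set(self.REQUIRED_COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValidationError(f"index is missing columns {sorted(missing)}")
        self.validate()

    def validate(self) -> None:
        df = self.frame
        for row_i, s in df["label"].items():
            DiliLabel.from_string(str(s))  # raises LabelingError naming the value
        for sid, g in df.groupby("sample_id", sort=False):
            days = np.sort(g["day"].unique())
            if not np.array_equal(days, np.arange(len(days))):
                raise ValidationError(f"sample {sid}: days {days.tolist()} are not contiguous from 0")
            z_per_day = g.groupby("day")["z"].nunique()
            if z_per_day.nunique() != 1:
                raise ValidationError(
                    f"sample {sid}: z-plane count differs across days ({dict(z_per_day)})"
                )
            if g["label"].nunique() != 1:
                raise ValidationError(f"sample {sid}: inconsistent labels")

    # -- per-sample views ---------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["sample_id"]))

    def label_of(self, sample_id: str) -> DiliLabel:
        s = self.frame.loc[self.frame["sample_id"] == sample_id, "label"].iloc[0]
        return DiliLabel.from_string(s)

    def labels(self) -> dict[str, DiliLabel]:
        return {sid: self.label_of(sid) for sid in self.sample_ids}

    def sample_table(self) -> pd.DataFrame:
        """One record per sample (sample_id, label, compound, platform)."""
        return (
            self.frame[["sample_id", "label", "compound", "platform"]]
            .drop_duplicates("sample_id")
            .reset_index(drop=True)
        )

    def paths_for(self, sample_id: str) -> pd.DataFrame:
        """The (day, z)-ordered path grid of one sample."""
        g = self.frame[self.frame["sample_id"] == sample_id]
        return g.sort_values(["day", "z"]).reset_index(drop=True)

    def resolve_paths(self) -> None:
        for p in self.frame["path"]:
            if not (self.base_dir / p).exists():
                raise OSError(f"image file not found: {self.base_dir / p}")

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def load_index(path: str | Path, check_files: bool = True) -> DatasetIndex:
    """Read and validate a CSV dataset index."""
    path = Path(path)
    if not path.exists():
        raise OSError(f"index file not found: {path}")
    df = pd.read_csv(path)
    index = DatasetIndex(df, base_dir=path.parent)
    if check_files:
        index.resolve_paths()
    return index


def _read_image(path: Path) -> np.ndarray:
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        return tifffile.imread(path)
    from PIL import Image

    return np.asarray(Image.open(path))


def load_stack(index: DatasetIndex, sample_id: str) -> OrganoidStack:
    """Materialize one sample's T x Z image grid from disk."""
    g = index.paths_for(sample_id)
    days = np.sort(g["day"].unique())
    zs = np.sort(g["z"].unique())
    first = _read_image(index.base_dir / g["path"].iloc[0])
    images = np.empty((len(days), len(zs)) + first.shape, dtype=np.float32)
    for _, row in g.iterrows():
        images[int(row["day"]), int(row["z"])] = _read_image(index.base_dir / row["path"])
    if np.issubdtype(first.dtype, np.integer):  # scale integer source data to [0, 1]
        images /= float(np.iinfo(first.dtype).max)
    return OrganoidStack(
        sample_id=sample_id,
        label=str(g["label"].iloc[0]),
        compound=str(g["compound"].iloc[0]),
        platform=str(g["platform"].iloc[0]),
        images=images,
        z_positions=zs.astype(float),
        day_indices=days,
    )


#: fixed per-channel standardization constants mapping [0, 1] -> [-1, 1]
NORM_MEAN = 0.5
NORM_STD = 0.5


def preprocess_image(
    raw: np.ndarray,
    out_size: int = 224,
    mean: float = NORM_MEAN,
    std: float = NORM_STD,
) -> np.ndarray:
    """Resize to `out_size` squared, replicate grayscale to 3 channels, and
    standardize with fixed constants.

    The raw image may be 2-D grayscale or H x W x 3, any spatial size, integer
    or float dtype. Integer inputs are scaled by their dtype maximum; float
    inputs are assumed to already lie in [0, 1] and are clipped.
    """
    arr = np.asarray(raw)
    if arr.size == 0:
        raise ValueError("empty image")
    if not np.isfinite(arr).all():
        raise ValueError("image contains non-finite pixels")
    if arr.ndim == 2:
        pass
    elif arr.ndim == 3 and arr.shape[2] == 3:
        pass
    else:
        raise ValueError(f"expected 2-D grayscale or HxWx3 image, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / float(np.iinfo(arr.dtype).max)
    else:
        arr = np.clip(arr.astype(np.float64), 0.0, 1.0)
    if arr.shape[:2] != (out_size, out_size):
        arr = _sk_resize(arr, (out_size, out_size), order=1, anti_aliasing=True, preserve_range=True)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    return ((arr - mean) / std).astype(np.float32)


def preprocess_stack(stack: OrganoidStack, out_size: int = 224) -> np.ndarray:
    """Preprocess every frame of a stack; returns (T, Z, out, out, 3) float32."""
    T, Z = stack.images.shape[:2]
    out = np.empty((T, Z, out_size, out_size, 3), dtype=np.float32)
    for t in range(T):
        for z in range(Z):
            out[t, z] = preprocess_image(stack.images[t, z], out_size=out_size)
    return out


def split_kfold(
    index: "DatasetIndex | pd.DataFrame | list",
    k: int = 5,
    seed: int = 0,
    stratify: bool = True,
    group_by: str | None = None,
) -> list[tuple[list[str], list[str]]]:
    """Partition sample ids into K cross-validation folds.

    Each sample appears in exactly one test fold; test folds have size n/K
    (+-1). Stratified by label by default; ``group_by="compound"`` switches to
    compound-disjoint folds (samples of one compound never straddle a split).
    """
    from sklearn.model_selection import GroupKFold, KFold, StratifiedGroupKFold, StratifiedKFold

    if isinstance(index, DatasetIndex):
        table = index.sample_table()
    elif isinstance(index, pd.DataFrame):
        table = index.drop_duplicates("sample_id").reset_index(drop=True)
    else:
        raise TypeError("index must be a DatasetIndex or a sample DataFrame")
    if k < 2:
        raise ConfigurationError("K must be >= 2")
    n = len(table)
    if k > n:
        raise ConfigurationError(f"K={k} exceeds the number of samples ({n})")
    ids = table["sample_id"].to_numpy()
    y = table["label"].to_numpy()
    groups = table[group_by].to_numpy() if group_by else None
    if stratify and groups is not None:
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        it = splitter.split(ids, y, groups)
    elif stratify:
        counts = pd.Series(y).value_counts()
        if counts.min() < k:
            raise ConfigurationError(
                f"stratified K={k} needs >= K samples per class (min is {counts.min()})"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        it = splitter.split(ids, y)
    elif groups is not None:
        it = GroupKFold(n_splits=k).split(ids, y, groups)
    else:
        it = KFold(n_splits=k, shuffle=True, random_state=seed).split(ids)
    return [(list(ids[tr]), list(ids[te])) for tr, te in it]
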