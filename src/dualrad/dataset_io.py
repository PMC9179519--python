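"""Reading BUSI-style image/mask directories and reproducible splits.

Directory layout: per-class folders (``benign/``, ``malignant/``, ``normal/``)
holding ``<name>.png`` images with ``<name>_mask.png`` ground-truth masks.
Several masks per image (``<name>_mask_1.png``, ...) are merged by pixelwise
OR, the conservative lesion support.  Normal-class images may lack a mask
file; an all-zero mask is substituted.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from PIL import Image

from .phantom import LABELS, UltrasoundSample


class DatasetError(ValueError):
    """Raised for malformed dataset directories or invalid split requests."""


@dataclass
class DatasetManifest:
    records: List[Tuple[str, str, str, Optional[str]]]  # (id, label, image path, mask path)
    class_counts: Dict[str, int] = field(default_factory=dict)


_MASK_RE = re.compile(r"^(?P<stem>.+?)_mask(?:_\d+)?\.png$", re.IGNORECASE)


def scan_dataset(root: str) -> DatasetManifest:
    """Index a BUSI-style directory without decoding any pixels."""
    if not os.path.isdir(root):
        raise DatasetError(f"dataset root {root!r} is not a directory")
    records = []
    counts: Dict[str, int] = {}
    for label in LABELS:
        folder = os.path.join(root, label)
        if not os.path.isdir(folder):
            continue
        names = sorted(os.listdir(folder))
        masks: Dict[str, List[str]] = {}
        images = []
        for name in names:
            if not name.lower().endswith(".png"):
                continue
            m = _MASK_RE.match(name)
            if m:
                masks.setdefault(m.group("stem"), []).append(os.path.join(folder, name))
            else:
                images.append(name[:-4])
        for stem in images:
            mask_paths = masks.get(stem)
            if mask_paths is None:
                if label != "normal":
                    raise DatasetError(f"missing mask for abnormal case {stem!r}")
                mask_entry = None
            else:
                mask_entry = ";".join(sorted(mask_paths))
            records.append((stem, label, os.path.join(folder, stem + ".png"), mask_entry))
            counts[label] = counts.get(label, 0) + 1
    if not records:
        raise DatasetError(f"no samples found under {root!r}")
    return DatasetManifest(records=records, class_counts=counts)


def _read_gray(path: str) -> np.ndarray:
    try:
        with Image.open(path) as im:
            return np.asarray(im.convert("L"), dtype=np.float64)
    except (OSError, ValueError) as e:
        raise DatasetError(f"unreadable image file {path!r}: {e}") from e


def _resize(arr: np.ndarray, size: int, nearest: bool) -> np.ndarray:
    if arr.shape == (size, size):
        return arr
    im = Image.fromarray(arr.astype(np.float32), mode="F")
    resample = Image.NEAREST if nearest else Image.BILINEAR
    return np.asarray(im.resize((size, size), resample=resample), dtype=np.float64)


def load_dataset(root: str, target_size: int = 512) -> List[UltrasoundSample]:
    """Load, resize to ``target_size`` square, and min-max normalize to [0, 1].

    Masks are resized with nearest-neighbor interpolation and re-binarized at
    0.5 so their supports stay crisp.
    """
    manifest = scan_dataset(root)
    samples = []
    for case_id, label, img_path, mask_entry in manifest.records:
        img = _read_gray(img_path)
        img = _resize(img, target_size, nearest=False)
        lo, hi = img.min(), img.max()
        img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
        if mask_entry is None:
            mask = np.zeros((target_size, target_size), dtype=np.uint8)
        else:
            merged = None
            for mp in mask_entry.split(";"):
                m = _read_gray(mp)
                merged = m if merged is None else np.maximum(merged, m)
            merged = _resize(merged, target_size, nearest=True)
            mask = (merged >= 0.5 * 255.0).astype(np.uint8) if merged.max() > 1 \
                else (merged >= 0.5).astype(np.uint8)
        if label != "normal" and not mask.any():
            raise DatasetError(f"abnormal case {case_id!r} has an empty mask")
        s = UltrasoundSample(id=case_id, image=img.astype(np.float32),
                             mask=mask, label=label)
        s.validate()
        samples.append(s)
    return samples


def split_dataset(samples: Sequence[UltrasoundSample], n_train: int, n_test: int,
                  seed: int = 0, stratify: bool = False,
                  ) -> Tuple[List[UltrasoundSample], List[UltrasoundSample]]:
    """Disjoint random train/test subsets of the requested sizes.

    With ``stratify`` the per-class proportions of the cohort are preserved in
    both partitions within rounding.  Deterministic under ``seed``.
    """
    n = len(samples)
    if n_train < 0 or n_test < 0 or n_train + n_test > n:
        raise DatasetError(
            f"requested split {n_train}+{n_test} exceeds cohort size {n}")
    rng = np.random.default_rng(seed)
    if not stratify:
        order = rng.permutation(n)
        train_idx = order[:n_train]
        test_idx = order[n_train:n_train + n_test]
    else:
        train_parts, test_parts = [], []
        labels = np.array([s.label for s in samples])
        # largest-remainder apportionment of the requested sizes across classes;
        # the test apportionment is capped by what the train take left over
        avail = {lab: int((labels == lab).sum()) for lab in sorted(set(labels))}
        quota_tr = {lab: n_train * c / n for lab, c in avail.items()}
        take_tr = _apportion(quota_tr, n_train, avail)
        quota_te = {lab: n_test * c / n for lab, c in avail.items()}
        take_te = _apportion(quota_te, n_test,
                             {lab: avail[lab] - take_tr[lab] for lab in avail})
        for lab in sorted(set(labels)):
            idx = np.where(labels == lab)[0]
            idx = idx[rng.permutation(len(idx))]
            if take_tr[lab] + take_te[lab] > len(idx):
                raise DatasetError(f"class {lab!r} too small for stratified split")
            train_parts.append(idx[:take_tr[lab]])
            test_parts.append(idx[take_tr[lab]:take_tr[lab] + take_te[lab]])
        train_idx = np.concatenate(train_parts) if train_parts else np.array([], int)
        test_idx = np.concatenate(test_parts) if test_parts else np.array([], int)
    train = [samples[i] for i in sorted(train_idx)]
    test = [samples[i] for i in sorted(test_idx)]
    return train, test


def _apportion(quotas: Dict[str, float], total: int,
               capacity: Dict[str, int]) -> Dict[str, int]:
    base = {k: min(int(np.floor(v)), capacity[k]) for k, v in quotas.items()}
    remainder = total - sum(base.values())
    order = sorted(quotas, key=lambda k: quotas[k] - base[k], reverse=True)
    while remainder > 0:
        progressed = False
        for k in order:
            if remainder == 0:
                break
            if base[k] < capacity[k]:
                base[k] += 1
                remainder -= 1
                progressed = True
        if not progressed:
            raise DatasetError("classes too small for the requested stratified split")
    return base


def write_split_csv(train: Sequence[UltrasoundSample],
                    test: Sequence[UltrasoundSample], path: str) -> None:
    rows = [{"id": s.id, "partition": "train"} for s in train]
    rows += [{"id": s.id, "partition": "test"} for s in test]
    pd.DataFrame(rows).to_csv(path, index=False)
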