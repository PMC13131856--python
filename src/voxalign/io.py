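"""NIfTI-1 volume I/O for paired-modality cohorts.

One file per subject per modality, named ``<iid>_<modality>.nii.gz``. Reads
are lossless round-trips of the data array and affine; subjects missing
either modality are reported (strict mode errors, lenient mode drops them
with a warning).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import nibabel as nib
import numpy as np

from .simdata import PairedVolumeCohort

__all__ = ["write_volumes", "read_volumes"]


def write_volumes(cohort: PairedVolumeCohort, out_dir, affine=None) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.eye(4)
    paths = []
    for i, iid in enumerate(cohort.subject_id):
        for mod, vols in (("a", cohort.vol_a), ("b", cohort.vol_b)):
            p = out_dir / f"{iid}_{mod}.nii.gz"
            nib.save(nib.Nifti1Image(vols[i].astype(np.float32), affine), p)
            paths.append(p)
    return paths


def read_volumes(in_dir, strict: bool = True) -> PairedVolumeCohort:
    in_dir = Path(in_dir)
    ids = sorted(
        {p.name.rsplit("_", 1)[0] for p in in_dir.glob("*_[ab].nii.gz")}
    )
    if not ids:
        raise FileNotFoundError(f"no '<iid>_<modality>.nii.gz' volumes in {in_dir}")
    kept, vols_a, vols_b = [], [], []
    missing = []
    for iid in ids:
        pa = in_dir / f"{iid}_a.nii.gz"
        pb = in_dir / f"{iid}_b.nii.gz"
        if not (pa.exists() and pb.exists()):
            missing.append(iid)
            continue
        try:
            ia, ib = nib.load(pa), nib.load(pb)
            va = np.asarray(ia.dataobj, dtype=np.float32)
            vb = np.asarray(ib.dataobj, dtype=np.float32)
        except Exception as exc:  # corrupt header names the file
            raise OSError(f"failed to read volume for {iid}: {exc}") from exc
        kept.append(iid)
        vols_a.append(va)
        vols_b.append(vb)
    if missing:
        if strict:
            raise FileNotFoundError(
                f"subjects missing one modality: {missing}"
            )
        warnings.warn(f"dropping subjects missing one modality: {missing}")
    shape = vols_a[0].shape
    return PairedVolumeCohort(kept, np.stack(vols_a), np.stack(vols_b), shape)
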