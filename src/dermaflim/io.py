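"""On-disk formats: HDF5 decay stacks, TIFF lifetime maps, JSON metadata.

One imaging site is stored as one HDF5 file with:

* dataset ``decays`` — unsigned-integer counts, shape ``(z, y, x, t)``;
* dataset ``depth_um`` — axial position per section, shape ``(z,)``;
* attributes ``time_bin_ns``, ``subject_id``, ``group``, ``site``,
  ``sg_depth_um``, ``sb_depth_um``.

Cohort-level metadata (subject ids, groups, clinical scores, generative
truth) lives in a single JSON file next to the site files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .decay import DecayCube, LifetimeMap
from .exceptions import FormatError
from .simulate import GroupParams, SiteStack, SyntheticSubject

__all__ = [
    "write_site_h5",
    "read_site_h5",
    "write_cohort",
    "read_cohort_metadata",
    "load_cohort",
    "write_lifetime_tiff",
]

_REQUIRED_DATASETS = ("decays", "depth_um")


def write_site_h5(path, subject: SyntheticSubject, site_label: str) -> None:
    """Write one imaging site of a subject to an HDF5 file."""
    stack = subject.sites[site_label]
    decays = np.stack([f.counts for f in stack.frames], axis=0)
    with h5py.File(path, "w") as fh:
        fh.create_dataset(
            "decays", data=decays, compression="gzip", compression_opts=1
        )
        fh.create_dataset("depth_um", data=stack.depths_um)
        fh.attrs["time_bin_ns"] = stack.frames[0].time_bin_ns
        fh.attrs["subject_id"] = subject.subject_id
        fh.attrs["group"] = stack.group_label
        fh.attrs["site"] = site_label
        fh.attrs["sg_depth_um"] = stack.sg_depth_um
        fh.attrs["sb_depth_um"] = stack.sb_depth_um


def read_site_h5(path) -> SiteStack:
    """Read one site file back into a :class:`SiteStack`."""
    with h5py.File(path, "r") as fh:
        for name in _REQUIRED_DATASETS:
            if name not in fh:
                raise FormatError(
                    f"{path}: missing required dataset {name!r}"
                )
        decays = fh["decays"][()]
        depths = fh["depth_um"][()]
        if decays.ndim != 4 or decays.shape[0] != depths.shape[0]:
            raise FormatError(
                f"{path}: decays must be (z, y, x, t) matching depth_um"
            )
        time_bin_ns = float(fh.attrs["time_bin_ns"])
        frames = [
            DecayCube(decays[z], time_bin_ns, depth_um=float(depths[z]))
            for z in range(decays.shape[0])
        ]
        return SiteStack(
            site_label=str(fh.attrs.get("site", "primary")),
            group_label=str(fh.attrs.get("group", "control")),
            frames=frames,
            sg_depth_um=float(fh.attrs.get("sg_depth_um", depths[0])),
            sb_depth_um=float(fh.attrs.get("sb_depth_um", depths[-1])),
        )


def _site_filename(subject_id: str, site_label: str) -> str:
    return f"{subject_id}__{site_label}.h5"


def write_cohort(
    out_dir, subjects: list[SyntheticSubject], truth_table=None
) -> Path:
    """Write all site files plus the cohort metadata JSON; returns its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"subjects": []}
    for subj in subjects:
        entry = {
            "subject_id": subj.subject_id,
            "group": subj.group_label,
            "pasi": subj.pasi,
            "lis": subj.lis,
            "sites": {},
            "truth": {
                label: dataclasses.asdict(params)
                for label, params in subj.truth.items()
            },
        }
        for site_label in subj.sites:
            fname = _site_filename(subj.subject_id, site_label)
            write_site_h5(out / fname, subj, site_label)
            entry["sites"][site_label] = fname
        meta["subjects"].append(entry)
    meta_path = out / "cohort.json"
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    if truth_table is not None:
        truth_table.to_csv(out / "truth.csv", index=False)
    return meta_path


def read_cohort_metadata(cohort_dir) -> dict:
    path = Path(cohort_dir) / "cohort.json"
    if not path.exists():
        raise FormatError(f"no cohort.json in {cohort_dir}")
    with open(path) as fh:
        return json.load(fh)


def load_cohort(cohort_dir) -> list[SyntheticSubject]:
    """Reassemble the in-memory subjects from a cohort directory."""
    meta = read_cohort_metadata(cohort_dir)
    root = Path(cohort_dir)
    subjects = []
    for entry in meta["subjects"]:
        sites = {
            label: read_site_h5(root / fname)
            for label, fname in entry["sites"].items()
        }
        truth = {
            label: GroupParams(**params)
            for label, params in entry.get("truth", {}).items()
        }
        subjects.append(
            SyntheticSubject(
                subject_id=entry["subject_id"],
                group_label=entry["group"],
                sites=sites,
                pasi=entry.get("pasi"),
                lis=entry.get("lis"),
                truth=truth,
            )
        )
    return subjects


def write_lifetime_tiff(path, lifetime_map: LifetimeMap) -> None:
    """Write a lifetime map as a 6-channel 32-bit TIFF.

    Channels: tau1, tau2, a1, a2, amplitude-weighted mean lifetime, mask.
    """
    channels = np.stack(
        [
            lifetime_map.tau1_ns,
            lifetime_map.tau2_ns,
            lifetime_map.a1,
            lifetime_map.a2,
            lifetime_map.mean_lifetime_ns,
            lifetime_map.mask.astype(np.float32),
        ]
    ).astype(np.float32)
    tifffile.imwrite(path, channels, metadata={"axes": "CYX"})
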