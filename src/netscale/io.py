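"""File I/O for cohorts and parcellation node tables.

Atlases and parcellations travel as NIfTI-1 integer label volumes (see
:mod:`netscale.atlas`); cohorts as one 4D NIfTI per subject plus a TSV
manifest (subject id, group) and per-subject nuisance TSVs; node tables and
feature tables as TSV.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import pandas as pd

from .atlas import LabelAtlas, save_label_volume
from .parcellation import ParcellationScheme
from .synthetic import SyntheticCohort

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_node_table",
    "save_parcellation",
]


def write_cohort(cohort: SyntheticCohort, out_dir: str, spacing=(3.0, 3.0, 3.0)) -> None:
    """Write one 4D NIfTI + nuisance TSV per subject and a group manifest."""
    os.makedirs(out_dir, exist_ok=True)
    affine = np.diag(list(spacing) + [1.0])
    rows = []
    for s in range(cohort.n_subjects):
        sid = f"sub-{s:03d}"
        nib.save(
            nib.Nifti1Image(cohort.series[s].astype(np.float32), affine),
            os.path.join(out_dir, f"{sid}_bold.nii.gz"),
        )
        pd.DataFrame(
            cohort.nuisance[s],
            columns=[f"nuis{j}" for j in range(cohort.nuisance[s].shape[1])],
        ).to_csv(os.path.join(out_dir, f"{sid}_nuisance.tsv"), sep="\t", index=False)
        rows.append({"subject": sid, "group": int(cohort.group[s])})
    pd.DataFrame(rows).to_csv(
        os.path.join(out_dir, "participants.tsv"), sep="\t", index=False
    )


def read_cohort(out_dir: str) -> SyntheticCohort:
    """Read a cohort written by :func:`write_cohort`."""
    manifest = pd.read_csv(os.path.join(out_dir, "participants.tsv"), sep="\t")
    series, nuisance = [], []
    for sid in manifest["subject"]:
        img = nib.load(os.path.join(out_dir, f"{sid}_bold.nii.gz"))
        series.append(np.asanyarray(img.dataobj).astype(np.float64))
        nuisance.append(
            pd.read_csv(
                os.path.join(out_dir, f"{sid}_nuisance.tsv"), sep="\t"
            ).to_numpy()
        )
    return SyntheticCohort(
        series=series,
        group=manifest["group"].to_numpy(),
        nuisance=nuisance,
        truth=frozenset(),
        spec=None,
    )


def write_node_table(parc: ParcellationScheme, path: str) -> None:
    """TSV node table: subregion id, parent id, voxel count, centroid (mm)."""
    rows = []
    for node in parc.node_ids:
        node = int(node)
        c = parc.centroids[node]
        rows.append(
            {
                "node": node,
                "parent": parc.parent_of[node],
                "n_voxels": int(np.count_nonzero(parc.labels == node)),
                "cx_mm": c[0],
                "cy_mm": c[1],
                "cz_mm": c[2],
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def save_parcellation(parc: ParcellationScheme, path: str) -> None:
    """Write the refined label grid as a NIfTI-1 integer volume."""
    save_label_volume(
        LabelAtlas(labels=parc.labels, spacing=parc.spacing), path
    )
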