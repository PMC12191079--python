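"""Feature-tensor persistence (NPZ and HDF5) and attention exports.

Both formats carry the same datasets — ``values``, ``labels``,
``subject_ids``, ``trial_ids``, ``feature_kind``, ``band_names`` — so
downstream stages cannot tell simulated fixtures from real extractions.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .features import FeatureTensor

__all__ = ["save_feature_tensor", "load_feature_tensor", "export_attention_csv"]


def save_feature_tensor(path, ft: FeatureTensor) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=ft.values)
            f.create_dataset("labels", data=ft.labels)
            f.create_dataset("subject_ids", data=ft.subject_ids)
            f.create_dataset("trial_ids", data=ft.trial_ids)
            f.attrs["feature_kind"] = ft.feature_kind
            f.attrs["band_names"] = list(ft.band_names)
    else:
        np.savez(
            path,
            values=ft.values,
            labels=ft.labels,
            subject_ids=ft.subject_ids,
            trial_ids=ft.trial_ids,
            feature_kind=np.array(ft.feature_kind),
            band_names=np.array(list(ft.band_names)),
        )


def load_feature_tensor(path) -> FeatureTensor:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            return FeatureTensor(
                values=f["values"][...],
                labels=f["labels"][...],
                subject_ids=f["subject_ids"][...],
                trial_ids=f["trial_ids"][...],
                feature_kind=str(f.attrs["feature_kind"]),
                band_names=tuple(str(b) for b in f.attrs["band_names"]),
            )
    with np.load(path, allow_pickle=False) as z:
        return FeatureTensor(
            values=z["values"],
            labels=z["labels"],
            subject_ids=z["subject_ids"],
            trial_ids=z["trial_ids"],
            feature_kind=str(z["feature_kind"]),
            band_names=tuple(str(b) for b in z["band_names"]),
        )


def export_attention_csv(path, electrode_labels, beta_mean, attention_mean=None) -> None:
    """Write per-electrode pooling weights (and optional per-layer mean
    attention row sums) keyed by electrode label."""
    beta_mean = np.asarray(beta_mean)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        header = ["electrode", "beta"]
        if attention_mean is not None:
            header += [f"layer{i}_row_sum" for i in range(len(attention_mean))]
        writer.writerow(header)
        for i, lab in enumerate(electrode_labels):
            row = [lab, f"{beta_mean[i]:.6g}"]
            if attention_mean is not None:
                row += [f"{a[i].sum():.6g}" for a in attention_mean]
            writer.writerow(row)
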