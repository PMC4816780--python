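"""File formats: HDF5 datasets and posteriors, JSON model cards, CSV tables.

Layouts
-------
ERF dataset (HDF5): ``/data`` (condition x sensor x time, float64),
``/time_ms``, ``/condition_names``, ``/leadfield/gain``; attributes
``sfreq_hz``, ``units``, ``subject_id``, ``seed``.

Posterior (HDF5): ``/mean``, ``/cov``, ``/F_trace``, ``/param_names``;
attributes ``F``, ``accuracy``, ``complexity``, ``converged``,
``model_id``, ``lam``, ``lam_var``.

Model card (JSON): sources, extrinsic matrices AF/AB, input weights C,
microcircuit parameters (kappa/gamma/r), and per-factor modulation blocks B.

Study bundle (directory): ``subject_XX.h5`` datasets, ``truth.json``
manifest, ``spec.yaml`` generating spec.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .microcircuit import (
    ExtrinsicTarget,
    IntrinsicTarget,
    MicrocircuitParams,
    ModulationSpec,
)
from .network import ERFDataset, LeadField, NetworkModel, Source
from .inversion import Posterior
from .selection import BMSResult, EvidenceTable
from .synth import StudyBundle, SyntheticStudySpec, generate_study

__all__ = [
    "save_dataset",
    "load_dataset",
    "model_card",
    "model_from_card",
    "save_model_card",
    "load_model_card",
    "save_posterior",
    "load_posterior",
    "save_evidence_csv",
    "load_evidence_csv",
    "save_bms_json",
    "save_study",
    "load_study",
]


# ---------------------------------------------------------------------------
# ERF datasets
# ---------------------------------------------------------------------------


def save_dataset(ds: ERFDataset, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ds.data, dtype="float64")
        f.create_dataset("time_ms", data=ds.times)
        f.create_dataset(
            "condition_names", data=np.array(ds.conditions, dtype=h5py.string_dtype())
        )
        if ds.leadfield is not None:
            g = f.create_group("leadfield")
            g.create_dataset("gain", data=ds.leadfield.gain)
            g.attrs["contribution"] = json.dumps(dict(ds.leadfield.contribution))
        f.attrs["sfreq_hz"] = ds.sfreq
        f.attrs["units"] = ds.units
        if ds.subject_id is not None:
            f.attrs["subject_id"] = ds.subject_id
        if ds.seed is not None:
            f.attrs["seed"] = int(ds.seed)
        if ds.truth is not None:
            f.attrs["truth"] = json.dumps(ds.truth)


def load_dataset(path) -> ERFDataset:
    with h5py.File(path, "r") as f:
        lf = None
        if "leadfield" in f:
            contribution = json.loads(f["leadfield"].attrs.get("contribution", "{}"))
            kwargs = {"contribution": contribution} if contribution else {}
            lf = LeadField(f["leadfield/gain"][()], **kwargs)
        return ERFDataset(
            data=f["data"][()],
            conditions=tuple(s.decode() if isinstance(s, bytes) else str(s)
                             for s in f["condition_names"][()]),
            times=f["time_ms"][()],
            sfreq=float(f.attrs["sfreq_hz"]),
            subject_id=str(f.attrs["subject_id"]) if "subject_id" in f.attrs else None,
            units=str(f.attrs.get("units", "a.u.")),
            leadfield=lf,
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
            truth=json.loads(f.attrs["truth"]) if "truth" in f.attrs else None,
        )


# ---------------------------------------------------------------------------
# Model cards
# ---------------------------------------------------------------------------


def _params_dict(p: MicrocircuitParams) -> dict:
    return {"kappa": dict(p.kappa), "gamma": dict(p.gamma), "r": p.sigmoid_slope}


def _params_from(d: dict) -> MicrocircuitParams:
    return MicrocircuitParams(
        kappa=d["kappa"], gamma=d["gamma"], sigmoid_slope=d.get("r", 2 / 3)
    )


def model_card(model: NetworkModel) -> dict:
    """Serialize a network model to a JSON-safe dict."""
    card = {
        "name": model.name,
        "sources": [
            {"name": s.name, "mni": list(s.mni), "level": s.level} for s in model.sources
        ],
        "AF": model.af.tolist(),
        "AB": model.ab.tolist(),
        "C": model.c.tolist(),
        "B": {},
    }
    if isinstance(model.params, list):
        card["params"] = [_params_dict(p) for p in model.params]
    else:
        card.update(_params_dict(model.params))
    for spec in model.modulations:
        card["B"][spec.factor] = {
            "extrinsic": [dataclasses.asdict(t) for t in spec.extrinsic],
            "intrinsic": [dataclasses.asdict(t) for t in spec.intrinsic],
            "activity_dependent": spec.activity_dependent,
        }
    return card


def model_from_card(card: dict) -> NetworkModel:
    sources = [Source(s["name"], tuple(s["mni"]), int(s["level"])) for s in card["sources"]]
    if "params" in card:
        params = [_params_from(d) for d in card["params"]]
    else:
        params = _params_from(card)
    mods = []
    for factor, block in card.get("B", {}).items():
        mods.append(
            ModulationSpec(
                factor=factor,
                extrinsic=[ExtrinsicTarget(**t) for t in block.get("extrinsic", [])],
                intrinsic=[IntrinsicTarget(**t) for t in block.get("intrinsic", [])],
                activity_dependent=bool(block.get("activity_dependent", False)),
            )
        )
    return NetworkModel(
        sources=sources,
        af=np.array(card["AF"], float),
        ab=np.array(card["AB"], float),
        c=np.array(card["C"], float),
        params=params,
        modulations=mods,
        name=card.get("name", "model"),
    )


def save_model_card(model: NetworkModel, path) -> None:
    Path(path).write_text(json.dumps(model_card(model), indent=2))


def load_model_card(path) -> NetworkModel:
    return model_from_card(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Posteriors
# ---------------------------------------------------------------------------


def save_posterior(post: Posterior, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("mean", data=post.mean)
        f.create_dataset("cov", data=post.cov)
        f.create_dataset("F_trace", data=post.f_trace)
        f.create_dataset(
            "param_names", data=np.array(post.param_names, dtype=h5py.string_dtype())
        )
        f.attrs.update(
            F=post.free_energy,
            accuracy=post.accuracy,
            complexity=post.complexity,
            converged=bool(post.converged),
            model_id=post.model_id,
            lam=post.lam,
            lam_var=post.lam_var,
            n_iter=post.n_iter,
        )


def load_posterior(path) -> Posterior:
    with h5py.File(path, "r") as f:
        return Posterior(
            mean=f["mean"][()],
            cov=f["cov"][()],
            param_names=[s.decode() if isinstance(s, bytes) else str(s)
                         for s in f["param_names"][()]],
            lam=float(f.attrs["lam"]),
            lam_var=float(f.attrs["lam_var"]),
            free_energy=float(f.attrs["F"]),
            accuracy=float(f.attrs["accuracy"]),
            complexity=float(f.attrs["complexity"]),
            f_trace=f["F_trace"][()],
            converged=bool(f.attrs["converged"]),
            model_id=str(f.attrs["model_id"]),
            n_iter=int(f.attrs["n_iter"]),
        )


# ---------------------------------------------------------------------------
# Evidence tables and BMS results
# ---------------------------------------------------------------------------


def save_evidence_csv(table: EvidenceTable, path) -> None:
    table.to_frame().to_csv(path, index_label="subject")


def load_evidence_csv(path) -> EvidenceTable:
    return EvidenceTable.from_frame(pd.read_csv(path, index_col="subject"))


def save_bms_json(result: BMSResult, path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2))


# ---------------------------------------------------------------------------
# Study bundles
# ---------------------------------------------------------------------------


def save_study(bundle: StudyBundle, directory, overwrite: bool = False) -> None:
    d = Path(directory)
    if d.exists() and any(d.iterdir()) and not overwrite:
        raise FileExistsError(f"{d} exists and is not empty (pass overwrite=True)")
    d.mkdir(parents=True, exist_ok=True)
    for i, ds in enumerate(bundle.datasets):
        save_dataset(ds, d / f"subject_{i:02d}.h5")
    (d / "truth.json").write_text(json.dumps(bundle.manifest, indent=2))
    (d / "spec.yaml").write_text(yaml.safe_dump(bundle.spec.to_dict()))


def load_study(directory) -> StudyBundle:
    d = Path(directory)
    spec = SyntheticStudySpec.from_dict(yaml.safe_load((d / "spec.yaml").read_text()))
    manifest = json.loads((d / "truth.json").read_text())
    datasets = [load_dataset(p) for p in sorted(d.glob("subject_*.h5"))]
    if not datasets:
        raise FileNotFoundError(f"no subject_*.h5 files in {d}")
    lf = datasets[0].leadfield
    if lf is None:
        raise ValueError("study datasets carry no lead field")
    return StudyBundle(spec=spec, leadfield=lf, datasets=datasets, manifest=manifest)
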