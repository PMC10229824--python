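"""File formats: cohort HDF5, ERP CSV, variant YAML, fit/PEB JSON."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .cohort import BlockRecord, CohortConfig, CohortDataset
from .inversion import FitResult, ParameterDensity
from .neural_mass import (
    EvokedResponse,
    ExtrinsicConnection,
    InputSpec,
    IntrinsicConnection,
    ModelVariant,
    Population,
    SourceArchitecture,
    SynapticKernel,
)

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_erp_csv",
    "read_erp_csv",
    "write_fit",
    "read_fit",
    "write_ground_truth",
    "read_ground_truth",
    "variant_to_yaml",
    "variant_from_yaml",
]


# ---------------------------------------------------------------------------
# model-variant YAML


def _variant_dict(v: ModelVariant) -> dict:
    return {
        "id": v.id,
        "sources": [
            {
                "name": s.name,
                "ii_self": s.ii_self,
                "populations": [{"label": p.label, "role": p.role}
                                for p in s.populations],
                "intrinsic_connections": [dataclasses.asdict(c)
                                          for c in s.intrinsic_connections],
                "exc_kernel": dataclasses.asdict(s.exc_kernel),
                "inh_kernel": dataclasses.asdict(s.inh_kernel),
            }
            for s in v.sources
        ],
        "extrinsic": [
            {**dataclasses.asdict(c),
             "target_populations": list(c.target_populations)}
            for c in v.extrinsic
        ],
        "input": {
            "onsets": list(v.input.onsets),
            "dispersions": list(v.input.dispersions),
            "amplitudes": list(v.input.amplitudes),
        },
    }


def variant_to_yaml(variant: ModelVariant, path: str | Path) -> None:
    """Serialize one model variant (architecture + extrinsic set) as YAML."""
    Path(path).write_text(yaml.safe_dump(_variant_dict(variant), sort_keys=False))


def variant_from_yaml(path: str | Path) -> ModelVariant:
    d = yaml.safe_load(Path(path).read_text())
    sources = tuple(
        SourceArchitecture(
            name=s["name"],
            populations=tuple(Population(**p) for p in s["populations"]),
            intrinsic_connections=tuple(IntrinsicConnection(**c)
                                        for c in s["intrinsic_connections"]),
            ii_self=s.get("ii_self", False),
            exc_kernel=SynapticKernel(**s["exc_kernel"]),
            inh_kernel=SynapticKernel(**s["inh_kernel"]),
        )
        for s in d["sources"]
    )
    extrinsic = tuple(
        ExtrinsicConnection(**{**c, "target_populations": tuple(c["target_populations"])})
        for c in d["extrinsic"]
    )
    inp = InputSpec(onsets=tuple(d["input"]["onsets"]),
                    dispersions=tuple(d["input"]["dispersions"]),
                    amplitudes=tuple(d["input"]["amplitudes"]))
    return ModelVariant(id=d["id"], sources=sources, extrinsic=extrinsic, input=inp)


# ---------------------------------------------------------------------------
# cohort HDF5 + sidecar CSV/JSON


def write_cohort(dataset: CohortDataset, out_dir: str | Path) -> Path:
    """One HDF5 per cohort plus covariate CSV and ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h5path = out / "cohort.h5"
    with h5py.File(h5path, "w") as f:
        f.attrs["seed"] = dataset.config.seed
        f.attrs["variant_id"] = dataset.variant_id
        f.attrs["output_rate_hz"] = 1000.0
        f.attrs["config_json"] = json.dumps(dataclasses.asdict(dataset.config))
        f.create_dataset("time_ms", data=dataset.time_ms)
        for r in dataset.records:
            g = f.create_group(f"subject_{r.subject}/block_{r.block}")
            g.attrs["freezing"] = r.freezing
            for region, erp in r.erp.items():
                gg = g.create_group(region)
                gg.create_dataset("erp", data=erp.amplitude)
                gg.create_dataset("trials", data=r.trials[region])
    dataset.covariates.to_csv(out / "covariates.csv", index=False)
    write_ground_truth(dataset, out / "ground_truth.json")
    return h5path


def read_cohort(path: str | Path) -> CohortDataset:
    path = Path(path)
    h5path = path / "cohort.h5" if path.is_dir() else path
    with h5py.File(h5path, "r") as f:
        config = CohortConfig(**json.loads(f.attrs["config_json"]))
        time_ms = f["time_ms"][:]
        gt = read_ground_truth(h5path.parent / "ground_truth.json")
        records = []
        for skey in sorted(f.keys(), key=lambda k: (k != "time_ms", k)):
            if not skey.startswith("subject_"):
                continue
            s = int(skey.split("_")[1])
            for bkey in f[skey]:
                b = int(bkey.split("_")[1])
                g = f[skey][bkey]
                erp, trials = {}, {}
                for region in g:
                    erp[region] = EvokedResponse(
                        region=region, time_ms=time_ms.copy(),
                        amplitude=g[region]["erp"][:],
                        n_trials=g[region]["trials"].shape[0])
                    trials[region] = g[region]["trials"][:]
                records.append(BlockRecord(
                    subject=s, block=b, freezing=float(g.attrs["freezing"]),
                    erp=erp, trials=trials,
                    true_theta=gt.get(f"{s}/{b}", {})))
        records.sort(key=lambda r: (r.subject, r.block))
        cov = pd.DataFrame([{"subject": r.subject, "block": r.block,
                             "freezing": r.freezing} for r in records])
        return CohortDataset(config=config, variant_id=str(f.attrs["variant_id"]),
                             records=records, covariates=cov, time_ms=time_ms)


def write_ground_truth(dataset: CohortDataset, path: str | Path) -> None:
    gt = {f"{r.subject}/{r.block}": r.true_theta for r in dataset.records}
    Path(path).write_text(json.dumps(gt, indent=1, sort_keys=True))


def read_ground_truth(path: str | Path) -> dict:
    p = Path(path)
    if not p.exists():
        return {}
    return json.loads(p.read_text())


# ---------------------------------------------------------------------------
# ERP CSV


def write_erp_csv(erp: EvokedResponse, path: str | Path) -> None:
    df = pd.DataFrame({"time_ms": erp.time_ms, "amplitude": erp.amplitude})
    with open(path, "w") as f:
        f.write(f"# region={erp.region} n_trials={erp.n_trials} "
                f"channel_id={erp.channel_id}\n")
        df.to_csv(f, index=False)


def read_erp_csv(path: str | Path) -> EvokedResponse:
    meta = {}
    with open(path) as f:
        header = f.readline()
        if header.startswith("#"):
            for tok in header[1:].split():
                k, _, v = tok.partition("=")
                meta[k] = v
            df = pd.read_csv(f)
        else:
            df = pd.read_csv(path)
    cid = meta.get("channel_id")
    return EvokedResponse(
        region=meta.get("region", "unknown"),
        time_ms=df["time_ms"].to_numpy(),
        amplitude=df["amplitude"].to_numpy(),
        n_trials=int(meta.get("n_trials", 1)),
        channel_id=None if cid in (None, "None") else int(cid))


# ---------------------------------------------------------------------------
# fit records


def write_fit(fit: FitResult, path: str | Path) -> None:
    rec = {
        "variant_id": fit.variant_id,
        "free_energy": fit.free_energy,
        "converged": fit.converged,
        "trace": list(map(float, fit.trace)),
        "posterior": {
            "names": list(fit.posterior.names),
            "mean": fit.posterior.mean.tolist(),
            "cov": fit.posterior.cov.tolist(),
            "lam": fit.posterior.lam,
            "lam_var": fit.posterior.lam_var,
        },
        "fitted": fit.fitted.tolist(),
        "components": {k: float(v) for k, v in fit.components.items()},
    }
    Path(path).write_text(json.dumps(rec))


def read_fit(path: str | Path) -> FitResult:
    rec = json.loads(Path(path).read_text())
    post = ParameterDensity(
        names=tuple(rec["posterior"]["names"]),
        mean=np.asarray(rec["posterior"]["mean"]),
        cov=np.asarray(rec["posterior"]["cov"]),
        lam=rec["posterior"]["lam"],
        lam_var=rec["posterior"]["lam_var"])
    fitted = np.asarray(rec["fitted"])
    return FitResult(posterior=post, free_energy=rec["free_energy"], fitted=fitted,
                     residuals=np.zeros_like(fitted), trace=rec["trace"],
                     converged=rec["converged"], variant_id=rec["variant_id"],
                     components=rec.get("components", {}))
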