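"""Plain-text readers/writers for the package's tabular interfaces.

Formats: plot tables and allocation plans as TSV, variance components and
run manifests as YAML, genotypes/kinships/pedigrees via their own classes
in :mod:`sparsegp.genotypes`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .me_mixed_model import VarianceComponents
from .sparse_design import AllocationPlan

PLOT_COLUMNS = ["line", "env", "year", "trial", "rep", "block", "row", "col", "value"]


def write_plot_table(df: pd.DataFrame, path, seed: int | None = None) -> None:
    """Write a plot table as TSV; the generating seed is recorded as a
    comment header line for provenance."""
    path = Path(path)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_plot_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_varcomp_yaml(vc: VarianceComponents, path) -> None:
    doc = {
        "sigma2": {k: float(v) for k, v in vc.sigma2.items()},
        "residual": {k: float(v) for k, v in vc.resid.items()},
        "loglik": float(vc.loglik),
        "n_iter": int(vc.n_iter),
        "converged": bool(vc.converged),
        "boundary": list(vc.boundary),
        "env_order": list(vc.env_order),
    }
    if vc.Lambda is not None:
        doc["Lambda"] = np.asarray(vc.Lambda).tolist()
        doc["Psi"] = np.asarray(vc.Psi).tolist()
        doc["Go"] = np.asarray(vc.Go).tolist()
    if vc.spatial_rho:
        doc["spatial_rho"] = {k: list(map(float, v)) for k, v in vc.spatial_rho.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_varcomp_yaml(path) -> VarianceComponents:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return VarianceComponents(
        sigma2=doc["sigma2"],
        resid=doc["residual"],
        Lambda=np.array(doc["Lambda"]) if "Lambda" in doc else None,
        Psi=np.array(doc["Psi"]) if "Psi" in doc else None,
        Go=np.array(doc["Go"]) if "Go" in doc else None,
        env_order=doc.get("env_order", []),
        spatial_rho={k: tuple(v) for k, v in doc.get("spatial_rho", {}).items()},
        loglik=doc.get("loglik", float("nan")),
        n_iter=doc.get("n_iter", 0),
        converged=doc.get("converged", True),
        boundary=tuple(doc.get("boundary", ())),
    )


def write_plan(plan: AllocationPlan, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fraction: {plan.overlap_fraction}\n")
        fh.write(f"# seed: {plan.seed}\n")
        fh.write(f"# overlap_count: {len(plan.overlap_set)}\n")
        plan.to_frame().to_csv(fh, sep="\t", index=False)


def write_yaml(doc: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
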