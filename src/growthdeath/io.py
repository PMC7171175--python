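"""File-format contracts: tidy CSVs, posterior outputs, run manifests."""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import validate_experiment_table
from .identifiability import validate_viability_assay
from .mcmc import PosteriorSamples

__all__ = [
    "read_experiment_table",
    "read_viability_assay",
    "write_truth_sidecar",
    "read_truth_sidecar",
    "write_posterior",
    "write_manifest",
]


def read_experiment_table(path) -> pd.DataFrame:
    """Read and validate a tidy three-channel measurement CSV."""
    return validate_experiment_table(pd.read_csv(path))


def read_viability_assay(path) -> pd.DataFrame:
    """Read and validate a (conc, replicate, viability) CSV."""
    return validate_viability_assay(pd.read_csv(path))


def write_truth_sidecar(path, values: dict) -> None:
    """Flat key = value sidecar recording a synthetic truth."""
    with open(path, "w") as fh:
        for k, v in values.items():
            fh.write(f"{k} = {v}\n")


def read_truth_sidecar(path) -> dict:
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        k, _, v = line.partition("=")
        try:
            out[k.strip()] = float(v)
        except ValueError:
            out[k.strip()] = v.strip()
    return out


def write_posterior(outdir, post: PosteriorSamples, stem: str = "posterior") -> None:
    """Posterior summary CSV plus a full-draw archive."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    post.summary().to_csv(outdir / f"{stem}_summary.csv", index=False)
    np.savez_compressed(
        outdir / f"{stem}_draws.npz",
        chain=post.chain,
        labels=np.array(post.labels),
        converged=np.array(post.converged),
    )


def read_posterior(path) -> PosteriorSamples:
    """Load a full-draw archive written by :func:`write_posterior`."""
    with np.load(path, allow_pickle=False) as data:
        return PosteriorSamples(
            labels=[str(s) for s in data["labels"]],
            chain=data["chain"],
            converged=bool(data["converged"]),
        )


def write_manifest(outdir, config: dict) -> None:
    """Reproducibility manifest: config echo, seed and versions."""
    import growthdeath

    manifest = {
        "config": {k: (str(v) if isinstance(v, Path) else v)
                   for k, v in config.items()},
        "versions": {
            "growthdeath": growthdeath.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(outdir).mkdir(parents=True, exist_ok=True)
    with open(Path(outdir) / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
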