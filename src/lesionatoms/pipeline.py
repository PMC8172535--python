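"""End-to-end driver: loads -> atoms -> design -> posterior -> reports.

``run_pipeline`` executes the full analysis on either a synthetic cohort
(a simulation config), a precomputed lesion-load matrix (CSV), or a
directory of binary lesion masks plus atlases, and writes every artifact
(tables, posterior draws, summaries, sex-difference and relevance maps)
into a run directory with provenance metadata (config hash, stage seeds,
package version).  Deterministic stages are byte-stable under an
unchanged config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import build_model_input
from .embedding import fit_nmf
from .inference import (ModelSpec, fit_hierarchical_model,
                        sex_difference_table, summarize_posterior)
from .parcellation import LesionLoadMatrix, compute_lesion_loads
from .relevance import backproject_relevance, cohort_summary_table
from .scheme import ParcelScheme, canonical_scheme
from .simulate import SimConfig, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _load_inputs(config: dict):
    """Stage 1: obtain the cohort table and lesion-load matrix."""
    if "simulate" in config:
        sim = SimConfig(**config["simulate"])
        cohort, loads, truth = generate_cohort(sim)
        return cohort, loads, truth
    if "loads_csv" in config:
        scheme = (ParcelScheme.from_csv(config["scheme_csv"])
                  if "scheme_csv" in config else canonical_scheme())
        loads = LesionLoadMatrix.from_csv(config["loads_csv"], scheme)
        cohort = pd.read_csv(config["cohort_csv"])
        return cohort, loads, None
    if "masks_dir" in config:
        import nibabel as nib

        scheme = (ParcelScheme.from_csv(config["scheme_csv"])
                  if "scheme_csv" in config else canonical_scheme())
        gm_img = nib.load(config["gm_atlas"])
        wm_img = nib.load(config["wm_atlas"])
        gm = np.asarray(gm_img.dataobj).astype(int)
        wm = np.asarray(wm_img.dataobj).astype(int)
        mask_paths = sorted(Path(config["masks_dir"]).glob("*.nii*"))
        rows, ids = [], []
        for path in mask_paths:
            img = nib.load(path)
            mask = np.asarray(img.dataobj)
            rows.append(compute_lesion_loads(
                mask, gm, wm, scheme,
                gm_affine=gm_img.affine, wm_affine=wm_img.affine,
                mask_affine=img.affine))
            ids.append(path.name.split("_")[0])
        voxel_ml = float(np.abs(np.linalg.det(gm_img.affine[:3, :3])) / 1000)
        loads = LesionLoadMatrix(ids, np.array(rows), scheme,
                                 voxel_volume_ml=voxel_ml or 0.001)
        cohort = pd.read_csv(config["cohort_csv"])
        return cohort, loads, None
    raise ValueError("config must provide 'simulate', 'loads_csv' or "
                     "'masks_dir'")


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> Path:
    """Run parcellate/simulate -> embed -> preprocess -> fit -> report.

    Parameters
    ----------
    config : dict or path to a YAML/JSON file
        Input block (``simulate`` | ``loads_csv`` | ``masks_dir``), an
        optional ``embedding`` block (``n_atoms``, ``seed``) and an
        optional ``model`` block (ModelSpec fields).
    out_dir : path
        Run directory; created if absent.

    Returns the run directory.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    if not isinstance(config, dict):
        text = Path(config).read_text()
        config = yaml.safe_load(text)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s "
                                           "%(name)s: %(message)s"))
    root = logging.getLogger("lesionatoms")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    cfg_hash = _config_hash(config)
    logger.info("pipeline start (config hash %s)", cfg_hash)

    try:
        cohort, loads, truth = _load_inputs(config)
        logger.info("inputs: %d patients x %d parcels", loads.n_patients,
                    loads.scheme.n_parcels)
    except Exception as exc:
        raise PipelineError("inputs", exc) from exc

    emb_cfg = config.get("embedding", {})
    try:
        decomp = fit_nmf(loads, n_atoms=emb_cfg.get("n_atoms", 10),
                         seed=emb_cfg.get("seed", 0))
        logger.info("embedding: %d atoms, relative error %.3f",
                    decomp.n_atoms, decomp.fit_metadata["relative_error"])
    except Exception as exc:
        raise PipelineError("embed", exc) from exc

    try:
        model_input, transform = build_model_input(cohort, decomp.scores,
                                                   return_transform=True)
    except Exception as exc:
        raise PipelineError("preprocess", exc) from exc

    model_cfg = dict(config.get("model", {}))
    spec = ModelSpec(**model_cfg)
    try:
        posterior = fit_hierarchical_model(model_input, spec)
        for w in posterior.diagnostics["warnings"]:
            logger.warning("sampler: %s", w)
    except Exception as exc:
        raise PipelineError("fit", exc) from exc

    try:
        summary = summarize_posterior(posterior)
        loads.to_csv(out_dir / "loads.csv")
        cohort.to_csv(out_dir / "cohort.csv", index=False)
        pd.DataFrame(decomp.basis,
                     columns=loads.scheme.names).to_csv(
            out_dir / "basis.csv", index=False)
        pd.DataFrame(decomp.scores).to_csv(out_dir / "scores.csv",
                                           index=False)
        transform.to_json(out_dir / "design_transform.json")
        posterior.to_dataframe().to_csv(out_dir / "posterior_draws.csv",
                                        index=False)
        summary.table.to_csv(out_dir / "posterior_summary.csv", index=False)
        cohort_summary_table(cohort).to_csv(out_dir / "cohort_summary.csv",
                                            index=False)
        if spec.hierarchy == "by_sex":
            sex_difference_table(posterior).to_csv(
                out_dir / "sex_differences.csv", index=False)
        for group in posterior.group_names:
            rel = backproject_relevance(posterior.atom_draws(group),
                                        decomp.basis, group=group,
                                        parcel_names=loads.scheme.names)
            rel.summary().to_csv(out_dir / f"relevance_{group}.csv",
                                 index=False)
        provenance = {
            "config": config,
            "config_hash": cfg_hash,
            "package_version": __version__,
            "embedding_metadata": {k: v for k, v in
                                   decomp.fit_metadata.items()
                                   if k != "error_trace"},
            "model_spec": {k: getattr(spec, k) for k in
                           ("hierarchy", "draws", "warmup", "chains",
                            "seed")},
            "diagnostics": {
                "acceptance_fraction":
                    posterior.diagnostics["acceptance_fraction"],
                "max_rhat": posterior.diagnostics["max_rhat"],
                "warnings": posterior.diagnostics["warnings"],
            },
        }
        (out_dir / "provenance.json").write_text(
            json.dumps(provenance, indent=2, default=str))
    except Exception as exc:
        raise PipelineError("report", exc) from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    logger.info("pipeline done: %s", out_dir)
    return out_dir
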