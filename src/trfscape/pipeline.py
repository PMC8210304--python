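"""End-to-end pipeline runner with a validated YAML configuration.

``run_pipeline`` wires the stages together (simulate -> build-ref ->
quantify -> cleavage -> differential -> subtyping -> drivers) according to
stage toggles, writes TSV outputs per stage, and stamps a provenance
manifest (seed, package version, input hashes) so a rerun with the same
configuration reproduces identical non-plot outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import yaml

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


_THRESHOLD_RANGES = {
    "filter_quantile": (0.0, 1.0),
    "filter_rpm": (0.0, float("inf")),
    "de_fdr": (0.0, 1.0),
    "de_fold_change": (1.0, float("inf")),
    "driver_min_cohorts": (1, 100),
}


@dataclass
class RunConfig:
    """Pipeline configuration; serializes losslessly to/from YAML."""

    out_dir: str
    seed: int = 0
    # inputs (ignored when simulate=True)
    trna_fasta: str | None = None
    fastq_dir: str | None = None
    metadata: str | None = None
    # stage toggles
    simulate: bool = True
    run_cleavage: bool = True
    run_de: bool = True
    run_subtyping: bool = False
    run_drivers: bool = False
    # thresholds
    filter_quantile: float = 0.9
    filter_rpm: float = 1.0
    de_fdr: float = 0.01
    de_fold_change: float = 2.0
    driver_min_cohorts: int = 2
    min_len: int = 15
    max_len: int = 30
    trailer_window: int = 50
    # simulation knobs forwarded to SimulationConfig
    sim: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name, (lo, hi) in _THRESHOLD_RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise PipelineError(f"config field {name}={v} outside [{lo}, {hi}]")
        if not 10 <= self.min_len <= self.max_len <= 35:
            raise PipelineError("length range must satisfy 10 <= min <= max <= 35")
        if not self.simulate:
            for attr in ("trna_fasta", "fastq_dir", "metadata"):
                path = getattr(self, attr)
                if path is None or not os.path.exists(path):
                    raise PipelineError(f"missing input path for {attr}: {path}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise PipelineError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict.

    Outputs land under ``config.out_dir`` in per-stage subdirectories; a
    stage failure halts the run with the stage name in the exception.
    """
    from . import __version__, annotation, differential, drivers, quantify
    from . import cleavage as clv
    from . import io as tio
    from . import simulate as sim

    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "stages": [],
        "input_hashes": {},
    }
    stage = "setup"
    try:
        if config.simulate:
            stage = "simulate"
            sim_cfg = sim.SimulationConfig(seed=config.seed, **config.sim)
            study = sim.simulate_study(sim_cfg)
            genes = study.genes
            libraries = study.libraries()
            samples = study.truth.samples
            ref_fasta = os.path.join(config.out_dir, "trna_genes.fasta")
            study.write_reference_fasta(ref_fasta)
            manifest["stages"].append(stage)
        else:
            stage = "load-inputs"
            genes = annotation.load_trna_fasta(
                config.trna_fasta, trailer_window=config.trailer_window
            )
            samples = tio.read_metadata(config.metadata)
            libraries = []
            for sid in samples.index:
                fq = os.path.join(config.fastq_dir, f"{sid}.fastq")
                if not os.path.exists(fq):
                    fq += ".gz"
                libraries.append(quantify.ReadLibrary.from_fastq(fq, sid))
            manifest["input_hashes"] = {
                "trna_fasta": _sha256(config.trna_fasta),
                "metadata": _sha256(config.metadata),
            }
            manifest["stages"].append(stage)

        stage = "build-ref"
        candidates = annotation.enumerate_trf_candidates(
            genes, (config.min_len, config.max_len)
        )
        ref_dir = os.path.join(config.out_dir, "reference")
        annotation.write_reference(candidates, ref_dir)
        manifest["stages"].append(stage)

        stage = "quantify"
        matrix = quantify.quantify_cohorts(libraries, candidates, samples)
        quant_dir = os.path.join(config.out_dir, "quantify")
        os.makedirs(quant_dir, exist_ok=True)
        tio.write_tsv_matrix(matrix.counts, os.path.join(quant_dir, "counts.tsv"),
                             index_label="trf")
        tio.write_tsv_matrix(matrix.rpm.round(4), os.path.join(quant_dir, "rpm.tsv"),
                             index_label="trf")
        with open(os.path.join(quant_dir, "qc.json"), "w") as fh:
            json.dump(getattr(matrix, "qc", {}), fh, indent=1, sort_keys=True)
        membership, filtered = quantify.filter_expressed(
            matrix, config.filter_quantile, config.filter_rpm
        )
        tio.write_tsv_matrix(membership.astype(int),
                             os.path.join(quant_dir, "expressed.tsv"),
                             index_label="trf")
        manifest["stages"].append(stage)

        if config.run_cleavage:
            stage = "cleavage"
            clv_dir = os.path.join(config.out_dir, "cleavage")
            os.makedirs(clv_dir, exist_ok=True)
            import pandas as pd

            for cls in (annotation.FIVE_PRIME, annotation.THREE_PRIME):
                profiles = clv.size_profile(filtered, cls)
                if profiles:
                    df = pd.DataFrame({g: d.e for g, d in profiles.items()},
                                      index=list(next(iter(profiles.values())).labels))
                    tio.write_tsv_matrix(df.T.round(6),
                                         os.path.join(clv_dir, f"size_profile_{cls}.tsv"),
                                         index_label="group")
                    if len(profiles) >= 2:
                        score = clv.js_cleavage_score(list(profiles.values()))
                        with open(os.path.join(clv_dir, f"js_{cls}.json"), "w") as fh:
                            json.dump({"js_cleavage_score_across_groups": score}, fh)
                landscape, conc = clv.position_landscape(filtered, cls)
                tio.write_tsv_matrix(landscape.round(6),
                                     os.path.join(clv_dir, f"landscape_{cls}.tsv"),
                                     index_label="family")
                conc.round(6).to_csv(os.path.join(clv_dir, f"concentration_{cls}.tsv"),
                                     sep="\t", header=True)
            manifest["stages"].append(stage)

        de_results = None
        if config.run_de:
            stage = "differential"
            de_dir = os.path.join(config.out_dir, "differential")
            os.makedirs(de_dir, exist_ok=True)
            de_results = differential.de_test_all(
                filtered,
                fdr_threshold=config.de_fdr,
                fc_threshold=config.de_fold_change,
            )
            de_results.round(6).to_csv(os.path.join(de_dir, "de.tsv"),
                                       sep="\t", index=False)
            per_cohort, recurrence = differential.dysregulation_summary(de_results)
            per_cohort.round(4).to_csv(os.path.join(de_dir, "summary.tsv"),
                                       sep="\t", index=False)
            recurrence.to_csv(os.path.join(de_dir, "recurrence.tsv"), sep="\t",
                              index_label="trf")
            manifest["stages"].append(stage)

        if config.run_subtyping:
            stage = "subtyping"
            from .subtyping import extract_signatures, nmf_consensus

            sub_dir = os.path.join(config.out_dir, "subtyping")
            os.makedirs(sub_dir, exist_ok=True)
            for cohort in filtered.cohorts:
                tumors = filtered.samples.index[
                    (filtered.samples["cohort"] == cohort)
                    & (filtered.samples["condition"] == "tumor")
                ]
                model = nmf_consensus(
                    filtered.subset(samples=tumors),
                    cohort=cohort,
                    trf_class=annotation.THREE_PRIME,
                    seed=config.seed,
                )
                model.assignments.to_csv(
                    os.path.join(sub_dir, f"{cohort}_assignments.tsv"),
                    sep="\t", header=True,
                )
                tio.write_tsv_matrix(
                    model.consensus.round(4),
                    os.path.join(sub_dir, f"{cohort}_consensus.tsv"),
                    index_label="sample",
                )
                sigs = extract_signatures(model, filtered.subset(samples=tumors))
                rows = [
                    {"subtype": s, "trf": t, "score": round(v, 4)}
                    for s, sig in sigs.signatures.items()
                    for t, v in sig
                ]
                import pandas as pd

                pd.DataFrame(rows, columns=["subtype", "trf", "score"]).to_csv(
                    os.path.join(sub_dir, f"{cohort}_signatures.tsv"),
                    sep="\t", index=False,
                )
            manifest["stages"].append(stage)

        if config.run_drivers:
            stage = "drivers"
            if de_results is None:
                raise PipelineError("driver screen requires the DE stage")
            drv_dir = os.path.join(config.out_dir, "drivers")
            os.makedirs(drv_dir, exist_ok=True)
            table = drivers.screen_drivers(
                de_results, filtered, min_cohorts=config.driver_min_cohorts
            )
            table.drop(columns=["per_cohort"]).to_csv(
                os.path.join(drv_dir, "drivers.tsv"), sep="\t", index_label="trf"
            )
            tissue = drivers.tissue_specificity(filtered)
            tissue.round(6).to_csv(os.path.join(drv_dir, "tissue_js.tsv"),
                                   sep="\t", header=True)
            manifest["stages"].append(stage)
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(f"stage {stage!r} failed: {err}") from err

    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    config.to_yaml(os.path.join(config.out_dir, "config.yaml"))
    return manifest
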