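"""End-to-end pipeline: FASTA -> NCD matrix -> clusters -> Newick tree.

A :class:`PipelineConfig` is serializable to a plain YAML file; the run
writes ``D.phylip``, ``clusters.json``, ``tree.nwk``, optionally
``alprox.tsv``, and a ``manifest.json`` recording versions, parameters,
seed and input digests so that a rerun from the manifest reproduces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import yaml

from . import __version__
from .alstats import ALParams, al_proximity
from .mac import MACParams, clusters_to_newick, mac_cluster
from .ncd import metric_report, ncd_matrix
from .seqio import read_fasta, write_distance_matrix

logger = logging.getLogger("ncdclust")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclasses.dataclass
class PipelineConfig:
    """Everything a pipeline run needs, serializable to YAML."""

    input: str
    outdir: str = "ncdclust_out"
    dialect: str = "max"
    sigma_filter: float = 2.0
    knn: int = 1
    tie_tol: float = 1e-9
    multiset_max: int = 3
    max_cycles: int = 5
    al_mode: str | None = None  # None disables the alprox.tsv stage
    threads: int = 1
    seed: int = 0
    log_level: str = "INFO"

    def mac_params(self) -> MACParams:
        return MACParams(
            sigma_filter=self.sigma_filter,
            knn=self.knn,
            tie_tol=self.tie_tol,
            multiset_max=self.multiset_max,
            max_cycles=self.max_cycles,
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run every stage and return a map from artifact name to path."""
    logging.basicConfig(level=config.log_level)
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    try:
        seqs = read_fasta(config.input)
    except Exception as exc:
        raise RuntimeError(f"[stage: read] {exc}") from exc
    logger.info("read %d sequences from %s", len(seqs), config.input)

    try:
        D = ncd_matrix(seqs, dialect=config.dialect, n_jobs=config.threads)
    except Exception as exc:
        raise RuntimeError(f"[stage: distance] {exc}") from exc
    dist_path = outdir / "D.phylip"
    write_distance_matrix(D, dist_path)
    artifacts["distance_matrix"] = str(dist_path)
    logger.info("distance matrix done in %.1fs", time.time() - t0)

    try:
        clustering = mac_cluster(D, config.mac_params())
    except Exception as exc:
        raise RuntimeError(f"[stage: cluster] {exc}") from exc
    report = metric_report(D)
    clusters_path = outdir / "clusters.json"
    with open(clusters_path, "w") as fh:
        payload = clustering.to_dict()
        payload["metric_report"] = {
            "max_self_distance": report.max_self_distance,
            "n_triples": report.n_triples,
            "n_triangle_violations": report.n_violations,
            "violation_fraction": report.violation_fraction,
        }
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    artifacts["clusters"] = str(clusters_path)

    try:
        newick = clusters_to_newick(clustering, D)
    except Exception as exc:
        raise RuntimeError(f"[stage: tree] {exc}") from exc
    tree_path = outdir / "tree.nwk"
    tree_path.write_text(newick + "\n")
    artifacts["tree"] = str(tree_path)

    if config.al_mode is not None:
        try:
            params = ALParams(mode=config.al_mode)
            rows = []
            for s in seqs:
                r = al_proximity(s, params)
                rows.append((s.id, len(s), r.O, r.E, r.sigma, r.z))
        except Exception as exc:
            raise RuntimeError(f"[stage: alprox] {exc}") from exc
        al_path = outdir / "alprox.tsv"
        with open(al_path, "w") as fh:
            fh.write("id\tn\tO\tE\tsigma\tz\n")
            for rid, n, O, E, sigma, z in rows:
                fh.write(f"{rid}\t{n}\t{O}\t{E:.6f}\t{sigma:.6f}\t{z:.6f}\n")
        artifacts["alprox"] = str(al_path)

    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "inputs": {config.input: _sha256(config.input)},
        "artifacts": sorted(artifacts),
        "n_sequences": len(seqs),
        "n_clusters": len(clustering.clusters),
        "n_singletons": len(clustering.singletons),
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    artifacts["manifest"] = str(manifest_path)
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return artifacts
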