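"""End-to-end confidence-gated docking pipeline.

Given a predicted complex with pLDDT in the B-factors, the pipeline
computes the confidence report and routes on interface-pLDDT: at or below
85 the predicted orientation is distrusted, so the ligand is randomized
and globally docked, the decoys clustered to five diverse low-energy
centers and each center refined by flexible local docking; above 85 local
refinement starts directly from the input coordinates. Mobile residues
for backbone sampling are the contiguous runs with pLDDT below 80. All
decoys are pooled and ranked by interface score.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import dockq as dockq_mod  # noqa: F401
from .dockq import DockQResult, dockq as dockq_eval, interface_rmsd as _interface_rmsd
from .confidence import (
    ConfidenceReport,
    GateParams,
    MobileSegments,
    Route,
    confidence_report,
    confusion_at_thresholds,
    roc_auc,
    select_mobile_residues,
)
from .redock import (
    ClusterSet,
    CoarseContactScore,
    Decoy,
    DecoySet,
    MoveParams,
    ReplicaLadder,
    cluster_decoys,
    rank_decoys,
    run_global_dock,
    run_local_dock,
)
from .structure_io import Partition, Structure, residue_plddt_profile, write_pdb
from .toys import ToyComplexSpec, generate_toy_complex  # re-exported fixture entry point

__all__ = [
    "PipelineConfig",
    "PipelineReport",
    "run_alphared",
    "evaluate_discriminator",
    "load_config",
    "generate_toy_complex",
    "ToyComplexSpec",
]

logger = logging.getLogger("alphared")


@dataclass
class PipelineConfig:
    partition_spec: str = "A_B"
    gate: GateParams = field(default_factory=GateParams)
    global_moves: MoveParams = field(default_factory=MoveParams.global_defaults)
    local_moves: MoveParams = field(default_factory=MoveParams.local_defaults)
    ladder: ReplicaLadder = field(default_factory=ReplicaLadder)
    n_steps_global: int = 2000
    n_steps_local: int = 1000
    cluster_k: int = 5
    cluster_cutoff: float = 5.0  # A ligand-RMSD
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_mapping(cls, kv: dict) -> "PipelineConfig":
        cfg = cls()
        gate_kw, cfg_kw = {}, {}
        gate_fields = {"interface_cutoff", "contact_cutoff", "gate_threshold",
                       "mobile_threshold", "min_segment_len"}
        for key, val in kv.items():
            if key in gate_fields:
                gate_kw[key] = type(getattr(GateParams(), key))(val)
            elif key in {"n_steps_global", "n_steps_local", "cluster_k", "seed"}:
                cfg_kw[key] = int(val)
            elif key in {"cluster_cutoff"}:
                cfg_kw[key] = float(val)
            elif key in {"partition_spec", "out_dir"}:
                cfg_kw[key] = str(val)
            else:
                raise KeyError(f"unknown config key {key!r}")
        if gate_kw:
            cfg_kw["gate"] = GateParams(**{**GateParams().__dict__, **gate_kw})
        for k, v in cfg_kw.items():
            setattr(cfg, k, v)
        return cfg


def load_config(path) -> PipelineConfig:
    """Parse a flat ``key = value`` text config (``#`` comments allowed)."""
    kv = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line without '=': {line!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        kv[key] = val
    return PipelineConfig.from_mapping(kv)


@dataclass
class PipelineReport:
    confidence: ConfidenceReport
    route: Route
    mobile_segments: MobileSegments
    clusters: ClusterSet | None
    ranked: list[Decoy]
    decoys: DecoySet
    model_dockq: DockQResult | None = None
    top_dockq: DockQResult | None = None

    def to_dict(self) -> dict:
        return {
            "confidence": self.confidence.to_dict(),
            "route": self.route.value,
            "mobile_segments": self.mobile_segments.segments,
            "n_clusters": len(self.clusters.centers) if self.clusters else 0,
            "n_decoys": len(self.ranked),
            "top_decoys": [
                {
                    "interface_score": d.interface_score,
                    "trajectory": d.trajectory,
                    "replica": d.replica,
                    "step": d.step,
                    "seed": d.seed,
                }
                for d in self.ranked[:10]
            ],
            "model_dockq": self.model_dockq.to_dict() if self.model_dockq else None,
            "top_dockq": self.top_dockq.to_dict() if self.top_dockq else None,
        }


def run_alphared(
    model: Structure,
    config: PipelineConfig = PipelineConfig(),
    native: Structure | None = None,
    score_fn: CoarseContactScore | None = None,
) -> PipelineReport:
    """Run the full confidence-gated docking protocol on a predicted complex."""
    if len(model.chains) < 2:
        raise ValueError("pipeline requires a multi-chain complex")
    partition = Partition.from_spec(config.partition_spec)
    report = confidence_report(model, partition, config.gate)
    route = report.gate
    profile = residue_plddt_profile(model)
    mobile = select_mobile_residues(profile, config.gate)
    logger.info(
        "gate: interface-pLDDT=%s route=%s mobile_segments=%d",
        f"{report.interface_plddt:.2f}" if report.interface_plddt is not None else "NA",
        route.value,
        len(mobile),
    )

    score = score_fn or CoarseContactScore()
    clusters: ClusterSet | None = None
    if route is Route.GLOBAL_DOCK:
        global_set = run_global_dock(
            model,
            partition,
            ladder=config.ladder,
            params=config.global_moves,
            n_steps=config.n_steps_global,
            seed=config.seed,
            score_fn=score,
        )
        clusters = cluster_decoys(global_set, config.cluster_cutoff, config.cluster_k)
        logger.info("global docking: %d decoys, %d cluster centers",
                    len(global_set), len(clusters.centers))
        per_center = max(1, config.n_steps_local // max(1, len(clusters.centers)))
        pooled: list[Decoy] = []
        for ci, center in enumerate(clusters.centers):
            local_set = run_local_dock(
                center.structure,
                partition,
                mobile=mobile,
                ladder=config.ladder,
                params=config.local_moves,
                n_steps=per_center,
                seed=(config.seed + 1000 * (ci + 1)) % 2**31,
                score_fn=score,
            )
            pooled.extend(local_set.decoys)
        decoy_set = DecoySet(decoys=pooled, template=global_set.template, partition=partition)
    else:
        decoy_set = run_local_dock(
            model,
            partition,
            mobile=mobile,
            ladder=config.ladder,
            params=config.local_moves,
            n_steps=config.n_steps_local,
            seed=config.seed,
            score_fn=score,
        )
    ranked = rank_decoys(decoy_set)
    logger.info("ranking: best interface score %.3f over %d decoys",
                ranked[0].interface_score, len(ranked))

    model_q = top_q = None
    if native is not None:
        model_q = dockq_eval(model, native, partition)
        top_q = dockq_eval(ranked[0].structure, native, partition)
    out = PipelineReport(
        confidence=report,
        route=route,
        mobile_segments=mobile,
        clusters=clusters,
        ranked=ranked,
        decoys=decoy_set,
        model_dockq=model_q,
        top_dockq=top_q,
    )
    if config.out_dir:
        _write_outputs(out, native, partition, Path(config.out_dir))
    return out


def _write_outputs(
    report: PipelineReport, native: Structure | None, partition: Partition, out_dir: Path
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, d in enumerate(report.ranked):
        name = f"decoy_{i:04d}.pdb"
        s = d.structure
        s.id = name[:-4]
        write_pdb(s, out_dir / name)
        row = {
            "decoy": name[:-4],
            "interface_score": f"{d.interface_score:.6f}",
            "trajectory": d.trajectory,
            "replica": d.replica,
            "step": d.step,
            "seed": d.seed,
        }
        if native is not None:
            q = dockq_eval(s, native, partition)
            row.update(
                fnat=f"{q.fnat:.4f}", irms=f"{q.irms:.4f}",
                lrms=f"{q.lrms:.4f}", dockq=f"{q.dockq:.4f}", capri=q.capri.value,
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_dir / "scorefile.tsv", sep="\t", index=False)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Discriminator evaluation
# ---------------------------------------------------------------------------

def evaluate_discriminator(
    entries: list[dict],
    params: GateParams = GateParams(),
    irmsd_threshold: float = 4.0,
) -> dict:
    """Evaluate the candidate docking-confidence metrics on a model cohort.

    Each entry provides ``model``, ``native`` and ``partition`` (a
    :class:`Partition` or spec string). For every model the four candidate
    metrics (interface residue count, interface contact count, average
    pLDDT, interface pLDDT) are computed; the binary label is near-native
    docking, iRMSD <= 4 A against the native. Returns per-metric ROC/AUC
    and the 85-threshold confusion matrix for interface-pLDDT.
    """
    if len(entries) < 2:
        raise ValueError("need at least two cohort entries")
    metrics: dict[str, list[float]] = {
        "interface_residues": [],
        "interface_contacts": [],
        "avg_plddt": [],
        "interface_plddt": [],
    }
    labels: list[int] = []
    irmsds: list[float] = []
    for e in entries:
        part = e["partition"]
        if isinstance(part, str):
            part = Partition.from_spec(part)
        rep = confidence_report(e["model"], part, params)
        metrics["interface_residues"].append(rep.n_interface_residues)
        metrics["interface_contacts"].append(rep.n_interface_contacts)
        metrics["avg_plddt"].append(rep.avg_plddt)
        metrics["interface_plddt"].append(
            rep.interface_plddt if rep.interface_plddt is not None else 0.0
        )
        irms = _interface_rmsd(e["model"], e["native"], part)
        irmsds.append(irms)
        labels.append(int(irms <= irmsd_threshold))
    if len(set(labels)) < 2:
        raise ValueError("cohort contains a single outcome class")
    result: dict = {"labels": labels, "irmsds": irmsds, "metrics": metrics, "roc": {}, "auc": {}}
    for name, scores in metrics.items():
        points, auc = roc_auc(scores, labels)
        result["roc"][name] = points
        result["auc"][name] = auc
    result["confusion"] = confusion_at_thresholds(
        metrics["interface_plddt"], irmsds, params, irmsd_threshold
    )
    return result
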