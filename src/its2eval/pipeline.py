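"""End-to-end orchestration: simulate -> annotate -> curate -> diverge -> identify.

One structured config drives all stages; every stochastic operation is
seeded from the global seed, so a rerun with the same config reproduces
byte-identical outputs.  Each stage writes its outputs under its own
subdirectory of the run directory, and a manifest records every file with
a content hash plus per-stage record counts.  A stage failure aborts the
run naming the failing stage; outputs of earlier stages are retained.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotate as ann
from . import curate as cur
from . import distances as dist
from . import identify as ident
from . import simulate as sim
from .io import SequenceRecord, read_fasta, read_taxonomy_table, write_fasta

STAGES = ("simulate", "annotate", "curate", "divergence", "identify", "report")


@dataclass
class PipelineConfig:
    """All stage parameters plus stage toggles and the global seed."""

    seed: int = 0
    out_dir: str = "its2eval_run"
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    simulation: sim.SimulationParams | None = None
    curation: cur.CurationConfig = field(default_factory=cur.CurationConfig)
    scoring: dist.AlignmentScoring = field(default_factory=dist.AlignmentScoring)
    max_evalue: float = 1.0
    profile_pseudocount: float = 1.0
    n_shuffles: int = 200
    leave_one_out: bool = True
    fold_incorrect_into_ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.simulation is None:
            self.simulation = sim.SimulationParams(seed=self.seed)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        seed = int(raw.get("seed", 0))
        sim_kwargs = dict(raw.get("simulation", {}))
        sim_kwargs.setdefault("seed", seed)
        cur_kwargs = dict(raw.get("curation", {}))
        if "unnamed_tokens" in cur_kwargs:
            cur_kwargs["unnamed_tokens"] = tuple(cur_kwargs["unnamed_tokens"])
        return cls(
            seed=seed,
            out_dir=raw.get("out_dir", "its2eval_run"),
            stages={**{s: True for s in STAGES}, **raw.get("stages", {})},
            simulation=sim.SimulationParams(**sim_kwargs),
            curation=cur.CurationConfig(**cur_kwargs),
            scoring=dist.AlignmentScoring(**raw.get("scoring", {})),
            max_evalue=raw.get("max_evalue", 1.0),
            profile_pseudocount=raw.get("profile_pseudocount", 1.0),
            n_shuffles=raw.get("n_shuffles", 200),
            leave_one_out=raw.get("leave_one_out", True),
            fold_incorrect_into_ambiguous=raw.get(
                "fold_incorrect_into_ambiguous", False),
        )

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "stages": dict(self.stages),
            "simulation": dataclasses.asdict(self.simulation),
            "curation": dataclasses.asdict(self.curation),
            "scoring": dataclasses.asdict(self.scoring),
            "max_evalue": self.max_evalue,
            "profile_pseudocount": self.profile_pseudocount,
            "n_shuffles": self.n_shuffles,
            "leave_one_out": self.leave_one_out,
            "fold_incorrect_into_ambiguous": self.fold_incorrect_into_ambiguous,
        }
        d["curation"]["unnamed_tokens"] = list(d["curation"]["unnamed_tokens"])
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in fixed order; returns the run manifest.

    A disabled stage is skipped and the next stage consumes the most recent
    upstream output (e.g. with curation off, divergence runs on the trimmed
    but uncurated sequences).
    """
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "files": {}}

    def register(stage: str, *paths: Path, **counts) -> None:
        manifest["stages"][stage] = {"status": "run", **counts}
        for p in paths:
            manifest["files"][str(p.relative_to(run_dir))] = _sha256(p)

    current_records: list[SequenceRecord] = []
    current_tax: pd.DataFrame | None = None
    dataset: sim.SimulatedDataset | None = None
    db: cur.ReferenceDatabase | None = None

    stage = "simulate"
    try:
        if config.stages.get("simulate", True):
            dataset = sim.simulate_dataset(config.simulation)
            paths = sim.write_dataset(dataset, run_dir / "simulate")
            register(stage, *paths.values(), n_records=len(dataset.records))
            current_records = dataset.records
            current_tax = dataset.taxonomy_table
        else:
            manifest["stages"][stage] = {"status": "skipped"}
            current_records = read_fasta(run_dir / "simulate" / "raw.fasta")
            current_tax = read_taxonomy_table(run_dir / "simulate" / "taxonomy.tsv")

        stage = "annotate"
        if config.stages.get("annotate", True):
            aln58 = dataset.alignment_5_8S if dataset else read_fasta(
                run_dir / "simulate" / "aln_5_8S.fasta")
            aln28 = dataset.alignment_28S if dataset else read_fasta(
                run_dir / "simulate" / "aln_28S.fasta")
            m58 = ann.build_profile(aln58, pseudocount=config.profile_pseudocount)
            m28 = ann.build_profile(aln28, pseudocount=config.profile_pseudocount)
            results, trimmed = ann.annotate_batch(
                current_records, m58, m28, max_evalue=config.max_evalue,
                calib_seed=config.seed, n_shuffles=config.n_shuffles)
            out = run_dir / "annotate"
            out.mkdir(exist_ok=True)
            write_fasta(trimmed, out / "trimmed.fasta")
            ann.annotation_report(results).to_csv(out / "annotation.tsv",
                                                  sep="\t", index=False)
            register(stage, out / "trimmed.fasta", out / "annotation.tsv",
                     n_in=len(current_records), n_annotated=len(trimmed))
            current_records = trimmed
        else:
            manifest["stages"][stage] = {"status": "skipped"}

        stage = "curate"
        if config.stages.get("curate", True):
            fungal_refs = dataset.fungal_refs if dataset else []
            fungal_profile = (ann.build_profile(fungal_refs)
                              if len(fungal_refs) >= 2 else None)
            db = cur.build_reference_db(
                current_records, current_tax, config.curation,
                fungal_profile=fungal_profile, fungal_refs=fungal_refs,
                scoring=config.scoring, calib_seed=config.seed)
            paths = db.save(run_dir / "curate")
            register(stage, *paths.values(), n_in=len(current_records),
                     n_kept=len(db.records),
                     n_rejected=len(current_records) - len(db.records))
            current_records = db.records
            current_tax = db.taxonomy_table
        else:
            manifest["stages"][stage] = {"status": "skipped"}

        stage = "divergence"
        if config.stages.get("divergence", True):
            out = run_dir / "divergence"
            out.mkdir(exist_ok=True)
            div = dist.divergence_table(current_records, current_tax,
                                        group_by="group", scoring=config.scoring)
            comp = dist.composition_summary(current_records, current_tax, "group")
            div.to_csv(out / "divergence_summary.tsv", sep="\t", index=False)
            comp.to_csv(out / "composition_summary.tsv", sep="\t", index=False)
            register(stage, out / "divergence_summary.tsv",
                     out / "composition_summary.tsv", n_records=len(current_records))
        else:
            manifest["stages"][stage] = {"status": "skipped"}

        stage = "identify"
        if config.stages.get("identify", True):
            if db is None:
                db = cur.ReferenceDatabase(
                    records=list(current_records),
                    taxonomy_table=current_tax[
                        current_tax["id"].isin({r.id for r in current_records})
                    ].reset_index(drop=True),
                    consensus={}, provenance=pd.DataFrame(
                        columns=["id", "decision", "reason"]))
            out = run_dir / "identify"
            out.mkdir(exist_ok=True)
            results, rep_sp = ident.evaluate_success(
                current_records, current_tax, db, group_by="group",
                level="species", leave_one_out=config.leave_one_out,
                scoring=config.scoring,
                fold_incorrect_into_ambiguous=config.fold_incorrect_into_ambiguous)
            reports = [rep_sp]
            for group_by, level in (("group", "genus"), ("family", "species"),
                                    ("genus", "species")):
                _, rep = ident.evaluate_success(
                    current_records, current_tax, db, group_by=group_by,
                    level=level, results=results, scoring=config.scoring,
                    fold_incorrect_into_ambiguous=config.fold_incorrect_into_ambiguous)
                reports.append(rep)
            ident.identification_table(results).to_csv(
                out / "identification.tsv", sep="\t", index=False)
            pd.concat(
                [r.rename(columns={r.columns[0]: "taxon"}).assign(grouping=g)
                 for r, g in zip(reports, ("group", "group", "family", "genus"))],
                ignore_index=True,
            ).to_csv(out / "success_report.tsv", sep="\t", index=False)
            register(stage, out / "identification.tsv",
                     out / "success_report.tsv", n_queries=len(current_records))
        else:
            manifest["stages"][stage] = {"status": "skipped"}

        stage = "report"
        if config.stages.get("report", True):
            path = make_report(run_dir)
            register(stage, path)
        else:
            manifest["stages"][stage] = {"status": "skipped"}
    except Exception as exc:
        (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                          default=str))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))
    return manifest


def _read_tsv(path: Path) -> pd.DataFrame | None:
    if not path.exists():
        return None
    return pd.read_csv(path, sep="\t")


def make_report(run_dir: str | Path) -> Path:
    """Assemble the stage TSVs into one markdown summary document.

    Sections: composition box-plot statistics, the six-metric divergence
    table, species/genus success rates per taxon set, and per-family and
    per-genus success breakdowns.  A missing stage output omits its
    section with a notice; the report never recomputes numbers.
    """
    run_dir = Path(run_dir)
    lines = ["# ITS2 barcode evaluation report", ""]

    def table(df: pd.DataFrame) -> str:
        return "```\n" + df.to_string(index=False) + "\n```"

    comp = _read_tsv(run_dir / "divergence" / "composition_summary.tsv")
    lines.append("## Sequence length and GC content")
    lines.append("")
    if comp is None:
        lines.append("_Composition summary not available (stage output missing)._")
    else:
        lines.append(table(comp))
    lines.append("")

    div = _read_tsv(run_dir / "divergence" / "divergence_summary.tsv")
    lines.append("## Intra- and inter-specific divergence (K2P)")
    lines.append("")
    if div is None:
        lines.append("_Divergence summary not available (stage output missing)._")
    else:
        pretty = div[["group"]].copy() if "group" in div else div.iloc[:, :1].copy()
        for metric in ("all_inter", "theta_prime", "min_inter",
                       "all_intra", "theta", "coalescent_depth"):
            mean, sd = div.get(f"{metric}_mean"), div.get(f"{metric}_sd")
            if mean is not None:
                pretty[metric] = [
                    "absent" if pd.isna(m) else f"{m:.4f} +/- {s:.4f}"
                    for m, s in zip(mean, sd)]
        lines.append(table(pretty))
    lines.append("")

    succ = _read_tsv(run_dir / "identify" / "success_report.tsv")
    lines.append("## Identification success by taxon set")
    lines.append("")
    if succ is None:
        lines.append("_Success report not available (stage output missing)._")
        lines.append("")
    else:
        top = succ[succ.grouping == "group"]
        lines.append(table(top))
        lines.append("")
        lines.append("## Success breakdown by family and genus")
        lines.append("")
        rest = succ[succ.grouping.isin(["family", "genus"])]
        if len(rest):
            lines.append(table(rest))
        else:
            lines.append("_No family/genus breakdown available._")
        lines.append("")

    out = run_dir / "report.md"
    out.write_text("\n".join(lines))
    return out
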