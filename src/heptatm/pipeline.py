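"""End-to-end modeling pipeline.

Stage order: template selection -> alignment generation along three routes
(PSA: sequence-sequence; MSA: target sequence vs. template family profile;
profile: family profile vs. family profile) -> best-route selection ->
anchored realignment -> reconciliation into a multi-template alignment ->
coordinate averaging -> membrane Z filtering -> optional evaluation
against a reference structure.

Every stage writes its product to the run directory in a standard format,
and a JSON run manifest records the inputs, configuration and seed, so a
run is reproducible byte-for-byte and each stage can be re-invoked
independently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .evaluation import rmsd_report
from .io_formats import (MembraneSlab, read_fasta, read_pdb_backbone,
                         load_manifest, write_alignment_fasta, write_pdb)
from .membrane import z_filter
from .multitemplate import (anchored_realign, choose_best_alignment,
                            locate_anchors, reconcile_alignments)
from .pairwise import global_align, percent_identity, select_templates
from .profiles import build_profile, one_hot_profile, profile_profile_align
from .scoring import blosum62
from .structure import average_model, transfer_gap_structure

logger = logging.getLogger(__name__)

ROUTES = ("psa", "msa", "profile", "auto")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    manifest: str                       # template-database manifest (YAML)
    out_dir: str = "run"
    route: str = "auto"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    pseudocount: float = 0.1
    slab: tuple[float, float] | None = None
    activation_state: str | None = None
    max_low_id_templates: int = 2
    homolog_dir: str | None = None      # <id>.fasta per sequence
    reference_pdb: str | None = None
    reference_chain: str = "A"
    skip_anchored: bool = False
    force_templates: list[str] = field(default_factory=list)
    alignment_file: str | None = None   # user-supplied MTA (gapped FASTA)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise ValueError(f"route must be one of {ROUTES}")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _homologs_for(config: PipelineConfig, seq_id: str):
    if config.homolog_dir is None:
        return []
    path = Path(config.homolog_dir) / f"{seq_id}.fasta"
    return read_fasta(path) if path.exists() else []


def run_pipeline(target_fasta, config: PipelineConfig) -> Path:
    """Run the full pipeline for the first sequence in *target_fasta*.

    Returns the run directory. Any stage failure raises StageError naming
    the stage; partial outputs are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = blosum62(config.gap_open, config.gap_extend)
    stage = "load-inputs"
    try:
        target = read_fasta(target_fasta)[0]
        templates = load_manifest(config.manifest)

        stage = "select-templates"
        if config.force_templates:
            by_id = {t.id: t for t in templates}
            chosen = []
            for tid in config.force_templates:
                if tid not in by_id:
                    raise ValueError(f"forced template {tid!r} not in manifest")
                aln = global_align(target, by_id[tid].sequence, scheme)
                chosen.append((by_id[tid], percent_identity(aln)))
        else:
            chosen = select_templates(target, templates, scheme,
                                      config.max_low_id_templates,
                                      config.activation_state)
        sel_lines = ["template_id\tpercent_identity"]
        sel_lines += [f"{t.id}\t{pid:.2f}" for t, pid in chosen]
        (out / "templates_selected.tsv").write_text("\n".join(sel_lines) + "\n")

        stage = "generate-alignments"
        target_homs = _homologs_for(config, target.id)
        p_target = build_profile(target, target_homs, scheme, config.pseudocount)
        p_target_seq = one_hot_profile(target)
        pairwise = []
        route_used = {}
        for tpl, _pid in chosen:
            tpl_homs = _homologs_for(config, tpl.id)
            p_tpl = build_profile(tpl.sequence, tpl_homs, scheme,
                                  config.pseudocount)
            candidates = []
            if config.route in ("psa", "auto"):
                candidates.append(("psa", global_align(target, tpl.sequence, scheme)))
            if config.route in ("msa", "auto"):
                candidates.append(("msa", profile_profile_align(
                    p_target_seq, p_tpl, scheme)))
            if config.route in ("profile", "auto"):
                candidates.append(("profile", profile_profile_align(
                    p_target, p_tpl, scheme)))
            route, aln = choose_best_alignment(candidates, p_target, p_tpl, scheme)
            route_used[tpl.id] = route

            if not config.skip_anchored and (tpl.anchors or tpl.ec2_cys is not None):
                anchors = locate_anchors(target, tpl, aln)
                aln = anchored_realign(target, tpl.sequence, anchors,
                                       aligner=lambda a, b: global_align(a, b, scheme),
                                       scheme=scheme)
            aln.id_a, aln.id_b = target.id, tpl.id
            write_alignment_fasta([(target.id, aln.row_a), (tpl.id, aln.row_b)],
                                  out / f"alignment_{tpl.id}.fasta")
            pairwise.append(aln)

        stage = "reconcile"
        if config.alignment_file:
            from .io_formats import read_alignment_fasta
            from .multitemplate import MultiTemplateAlignment
            rows = read_alignment_fasta(config.alignment_file)
            mta = MultiTemplateAlignment(rows[0][0], rows[0][1],
                                         [r[0] for r in rows[1:]],
                                         [r[1] for r in rows[1:]])
        else:
            mta = reconcile_alignments(target, pairwise)
        write_alignment_fasta(
            [(mta.target_id, mta.target_row)]
            + list(zip(mta.template_ids, mta.template_rows)),
            out / "mta.fasta")

        stage = "average-model"
        chosen_templates = [t for t, _ in chosen]
        model = average_model(mta, chosen_templates, scheme=scheme)
        write_pdb(model, out / "model.pdb")
        bulges = transfer_gap_structure(mta, chosen_templates, scheme=scheme)
        blines = ["tm\tkind\ttarget_pos\tinherited_from\tinherited\tpattern"]
        for b in bulges:
            pat = ",".join(f"{k}:{v}" for k, v in sorted(b.pattern.items()))
            blines.append(f"{b.tm}\t{b.kind}\t{b.target_position + 1}\t"
                          f"{b.inherited_from}\t{b.inherited}\t{pat}")
        (out / "bulges.tsv").write_text("\n".join(blines) + "\n")

        stage = "z-filter"
        slab = (MembraneSlab(*config.slab) if config.slab is not None
                else model.frame)
        verdict = z_filter(model, slab)
        flines = ["model\tpassed\tn_offenders"]
        flines.append(f"{model.id}\t{verdict.passed}\t{len(verdict.offenders)}")
        for idx, label, zval in verdict.offenders:
            flines.append(f"# offender\t{idx + 1}\t{label}\t{zval:.3f}")
        (out / "filter.tsv").write_text("\n".join(flines) + "\n")

        evaluation = None
        if config.reference_pdb:
            stage = "evaluate"
            ref = read_pdb_backbone(config.reference_pdb, config.reference_chain)
            n = min(len(model.residues), len(ref.residues))
            corr = [(i, i) for i in range(n)
                    if model.residues[i].ca is not None
                    and ref.residues[i].ca is not None]
            report = rmsd_report(model, ref, corr)
            evaluation = report.to_dict()
            (out / "evaluation.json").write_text(
                json.dumps(evaluation, indent=2, sort_keys=True) + "\n")

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "target": {"id": target.id, "length": len(target),
                       "sha256": _sha256(Path(target_fasta))},
            "template_manifest_sha256": _sha256(Path(config.manifest)),
            "config": dataclasses.asdict(config),
            "selected_templates": [[t.id, round(pid, 4)] for t, pid in chosen],
            "route_used": route_used,
            "filter_passed": verdict.passed,
            "evaluation": evaluation,
            "seed": config.seed,
        }
        (out / "run_manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc
    return out
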