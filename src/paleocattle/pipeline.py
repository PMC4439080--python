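"""End-to-end orchestration: QC, haplotypes, classification, diversity,
network and cohort tests.

The replication QC implements the ancient-DNA authentication rule used for
the sequence panel: a (sample, fragment) passes only when at least three
amplifications yield an identical sequence and those amplifications span at
least two independent extractions and two laboratories (all three thresholds
configurable).  ``run_pipeline`` chains the stages over one alignment plus
metadata and writes the per-cohort diversity table, the haplotype network
and the cohort test results into an output directory, logging sample counts
at every filter so attrition is traceable.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import __version__
from .cohort_tests import select_test
from .diversity import HeterochronyParams, cohort_summary
from .haplogroups import (
    NO_AMPLIFICATION,
    YHaplotypeCall,
    batch_classify,
    default_ruleset,
    load_ruleset,
)
from .haplotyping import (
    ContingencyTable,
    assign_period,
    build_counts,
    collapse_haplotypes,
)
from .network import annotate_nodes, build_mjn, export_network
from .seqio import (
    AlignedSeqSet,
    RegionSpec,
    SampleRecord,
    read_alignment,
    read_metadata,
    sample_age,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AmpliconRecord:
    """One sequenced amplification of one fragment of one sample."""

    sample_id: str
    fragment: str
    extraction_id: str
    lab_id: str
    amplification_id: str
    sequence: str

    def __post_init__(self) -> None:
        for name in ("sample_id", "fragment", "extraction_id", "lab_id", "amplification_id"):
            if not getattr(self, name):
                raise ValueError(f"empty {name}")


@dataclass(frozen=True)
class ReplicationPolicy:
    """Replication thresholds (defaults: 3 amplifications, 2 extractions, 2 labs)."""

    min_amplifications: int = 3
    min_extractions: int = 2
    min_labs: int = 2


@dataclass
class ConsensusResult:
    sample_id: str
    fragment: str
    passed: bool
    consensus: str | None
    reason: str


def replication_consensus(
    records: Sequence[AmpliconRecord], policy: ReplicationPolicy = ReplicationPolicy()
) -> dict[tuple[str, str], ConsensusResult]:
    """Per (sample, fragment) replication verdicts.

    Pass iff some sequence is supported by >= min_amplifications identical
    amplicons spanning >= min_extractions extractions and >= min_labs labs;
    the consensus is that agreed sequence.  Failures carry a reason.
    """
    grouped: dict[tuple[str, str], list[AmpliconRecord]] = {}
    for rec in records:
        grouped.setdefault((rec.sample_id, rec.fragment), []).append(rec)

    out: dict[tuple[str, str], ConsensusResult] = {}
    for key, amps in grouped.items():
        sid, frag = key
        if len(amps) < policy.min_amplifications:
            out[key] = ConsensusResult(sid, frag, False, None, "insufficient replicates")
            continue
        by_seq = Counter(a.sequence for a in amps)
        candidates = [
            s for s, c in by_seq.most_common() if c >= policy.min_amplifications
        ]
        result = None
        for seq in candidates:
            support = [a for a in amps if a.sequence == seq]
            n_ext = len({a.extraction_id for a in support})
            n_lab = len({a.lab_id for a in support})
            if n_ext < policy.min_extractions:
                result = ConsensusResult(sid, frag, False, None, "insufficient extractions")
            elif n_lab < policy.min_labs:
                result = ConsensusResult(sid, frag, False, None, "insufficient laboratories")
            else:
                result = ConsensusResult(sid, frag, True, seq, "replicated")
                break
        out[key] = result or ConsensusResult(sid, frag, False, None, "discordant")
    return out


def sex_concordance(
    samples: Sequence[SampleRecord], ycalls: Sequence[YHaplotypeCall]
) -> ContingencyTable:
    """Cross-tab of osteological sex against Y-chromosomal amplification.

    Discordant cells (females that amplified) indicate contamination or
    mis-sexing and are logged.
    """
    status = {c.sample_id: c.label != NO_AMPLIFICATION for c in ycalls}
    rows = sorted({s.sex for s in samples})
    counts = [[0, 0] for _ in rows]
    for s in samples:
        amplified = status.get(s.id, False)
        counts[rows.index(s.sex)][0 if amplified else 1] += 1
        if s.sex == "female" and amplified:
            logger.warning("sample %s: female metacarpal with Y amplification", s.id)
    return ContingencyTable(rows, ["amplified", "not_amplified"], counts)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    alignment_path: str | Path
    region: RegionSpec
    metadata_path: str | Path
    output_dir: str | Path
    seed: int
    ruleset_path: str | Path | None = None
    missing_policy: str = "complete_deletion"
    epsilon: int = 0
    mutation_rate_per_myr: float = 0.43    # substitutions / site / Myr
    generation_length: float = 5.0          # years
    min_cohort_size: int = 4                # below this, no D / no summary row


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(cfg: RunConfig) -> dict:
    """Run collapse -> classify -> diversity -> network -> cohort tests.

    Writes haplotypes.tsv, classification.tsv, diversity.tsv, network.graphml,
    network_edges.tsv, cohort_counts.tsv, cohort_test.json and run_log.json
    into ``cfg.output_dir``; returns the report dict.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "version": __version__, "stages": {}}

    def stage(name):
        logger.info("pipeline stage: %s", name)
        report["stages"][name] = {}
        return report["stages"][name]

    try:
        info = stage("load")
        aln = read_alignment(cfg.alignment_path, cfg.region)
        samples = read_metadata(cfg.metadata_path)
        by_id = {s.id: s for s in samples}
        missing_meta = [i for i in aln.ids if i not in by_id]
        if missing_meta:
            logger.warning("%d sequences without metadata dropped: %s",
                           len(missing_meta), missing_meta)
            aln = aln.subset([i for i in aln.ids if i in by_id])
        info.update(n_sequences=len(aln), n_metadata=len(samples),
                    n_dropped_no_metadata=len(missing_meta))
    except Exception as exc:  # noqa: BLE001
        raise StageError("load", exc) from exc

    try:
        info = stage("haplotypes")
        table = collapse_haplotypes(aln, cfg.missing_policy)
        table.write(out / "haplotypes.tsv")
        info.update(n_haplotypes=len(table), n_samples=table.n_samples)
    except Exception as exc:  # noqa: BLE001
        raise StageError("haplotypes", exc) from exc

    try:
        info = stage("classify")
        rules = load_ruleset(cfg.ruleset_path) if cfg.ruleset_path else default_ruleset()
        calls = batch_classify(aln, rules)
        calls.to_csv(out / "classification.tsv", sep="\t", index=False)
        info.update(label_counts=calls["label"].value_counts().to_dict())
    except Exception as exc:  # noqa: BLE001
        raise StageError("classify", exc) from exc

    try:
        info = stage("diversity")
        periods: dict[str, list[str]] = {}
        for sid in aln.ids:
            periods.setdefault(assign_period(by_id[sid]), []).append(sid)
        rows = []
        for period in sorted(periods, key=lambda p: [b[0] for b in _period_order].index(p)
                             if p in [b[0] for b in _period_order] else 99):
            ids = periods[period]
            if len(ids) < cfg.min_cohort_size:
                logger.info("cohort %s: only %d samples, skipped", period, len(ids))
                continue
            sub = aln.subset(ids)
            ages = tuple(sample_age(by_id[i], cfg.seed) for i in ids)
            params = HeterochronyParams(
                rate=cfg.mutation_rate_per_myr, ages=ages,
                generation_length=cfg.generation_length,
            )
            est = cohort_summary(sub, params)
            rows.append({"cohort": period, **est.as_dict()})
        # pooled cohort
        ages = tuple(sample_age(by_id[i], cfg.seed) for i in aln.ids)
        est = cohort_summary(
            aln,
            HeterochronyParams(rate=cfg.mutation_rate_per_myr, ages=ages,
                               generation_length=cfg.generation_length),
        )
        rows.append({"cohort": "Total", **est.as_dict()})
        div = pd.DataFrame(rows)
        div.to_csv(out / "diversity.tsv", sep="\t", index=False)
        info.update(cohorts=[r["cohort"] for r in rows])
    except Exception as exc:  # noqa: BLE001
        raise StageError("diversity", exc) from exc

    try:
        info = stage("network")
        net = build_mjn(table, cfg.epsilon)
        annotate_nodes(net, samples)
        export_network(net, out / "network.graphml", out / "network_edges.tsv")
        info.update(n_nodes=net.number_of_nodes(), n_edges=net.number_of_edges())
    except Exception as exc:  # noqa: BLE001
        raise StageError("network", exc) from exc

    try:
        info = stage("cohort_tests")
        aln_samples = [by_id[i] for i in aln.ids]
        counts = build_counts(
            aln_samples,
            row_by=assign_period,
            col_by=lambda rec: table.label_of(rec.id),
        )
        counts.write(out / "cohort_counts.tsv")
        result = None
        if min(counts.shape) >= 2:
            result = select_test(counts)
            (out / "cohort_test.json").write_text(json.dumps(result.as_dict(), indent=2))
            info.update(result.as_dict())
        info.update(table_shape=list(counts.shape), n=counts.total)
    except Exception as exc:  # noqa: BLE001
        raise StageError("cohort_tests", exc) from exc

    (out / "run_log.json").write_text(json.dumps(report, indent=2, default=str))
    return report


_period_order = (
    ("Prehistoric",), ("Medieval",), ("Post-Medieval",), ("Modern",),
)
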