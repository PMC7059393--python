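"""End-to-end pipeline: stage plumbing, configuration and the demo.

The demo simulates the study design's three arms from one global seed —

* **MSC-like**: moderate Wright–Fisher bottleneck per passage (gradual
  diversity decline),
* **iPSC-like**: large bottleneck (near-stable composition),
* **iMSC-like**: a differentiation bottleneck of a few recruited founders
  followed by expansion (abrupt oligoclonality) —

then runs barcode extraction, clone counting, diversity and methylation
pattern analysis on the synthetic reads, writing TSV/JSON reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import clones as cl
from . import dilution as dil
from . import extract as ex
from . import methylation as meth
from . import simulate as sim
from .core import ColorTag, DEFAULT_TAGS, SampleMeta, validate_tags

log = logging.getLogger("clonotrace")


@dataclass
class PipelineConfig:
    """Demo/pipeline parameters; round-trips through key=value text."""

    seed: int = 0
    # Low-MOI labeling: ~99.5% of puromycin-selected founders carry a single
    # integration, so barcode clones coincide with cell clones and the
    # demo's diversity readout tracks cell clonality directly.  ~300
    # founders survive selection in expectation.
    n_cells: int = 30000        # cells exposed to virus per arm
    moi: float = 0.01           # mean integrations per cell before selection
    fitness_sd: float = 0.0     # lognormal log-sd of clone growth weights
    growth_factor: float = 4.0
    msc_bottleneck: int = 500
    msc_passages: int = 6
    ipsc_bottleneck: int = 2000
    ipsc_passages: int = 10
    imsc_split_passage: int = 3  # iPSC passage at which differentiation starts
    imsc_recruited: int = 3      # founders recruited into the iMSC lineage
    imsc_passages: int = 5
    read_count: int = 3000       # barcode reads sequenced per sampled passage
    seq_error_rate: float = 0.0  # demo reads are error-free; error collapse
                                 # is exercised by the library's own tests
    collapse: bool = True
    n_cpgs: int = 7              # CASR-like amplicon for the methylation readout
    flip_rate: float = 0.01      # per-passage per-CpG epimutation probability
    meth_reads: int = 2000
    dilution_true_f: float = 0.058
    log_level: str = "INFO"

    def to_text(self) -> str:
        lines = [f"{f.name} = {getattr(self, f.name)}"
                 for f in dataclasses.fields(self)]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"config line {lineno}: expected key = value")
            key, _, value = (s.strip() for s in line.partition("="))
            if key not in fields:
                raise ValueError(f"config line {lineno}: unknown key {key!r}")
            ftype = fields[key].type
            if ftype in ("int", int):
                kwargs[key] = int(value)
            elif ftype in ("float", float):
                kwargs[key] = float(value)
            elif ftype in ("bool", bool):
                kwargs[key] = value.lower() in {"1", "true", "yes"}
            else:
                kwargs[key] = value
        return cls(**kwargs)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed, stable across reruns.

    Derivation: ``SeedSequence(global_seed, spawn_key=(crc32(stage),))``,
    reduced below 2**31 so it can feed any RNG API.
    """
    ss = np.random.SeedSequence(global_seed, spawn_key=(zlib.crc32(stage.encode()),))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _file_md5(path: Path) -> str:
    h = hashlib.md5()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def load_tags(path) -> tuple[ColorTag, ...]:
    df = pd.read_csv(path, sep="\t")
    tags = tuple(ColorTag(str(r.name), str(r.sequence))
                 for r in df.itertuples(index=False))
    validate_tags(tags)
    return tags


# ---------------------------------------------------------------------------
# simulation arms

def simulate_arm(arm: str, config: PipelineConfig) -> list[sim.PopulationState]:
    """Population trajectory of one demo arm, seeded from the global seed."""
    seed = stage_seed(config.seed, f"label:{arm}")
    founders = sim.simulate_labeling(config.n_cells, config.moi,
                                     fitness_sd=config.fitness_sd, seed=seed)
    start = sim.initial_state(founders)
    pseed = stage_seed(config.seed, f"passage:{arm}")
    if arm == "MSC":
        return sim.simulate_passaging(start, config.msc_passages,
                                      config.msc_bottleneck,
                                      config.growth_factor, pseed)
    if arm == "iPSC":
        return sim.simulate_passaging(start, config.ipsc_passages,
                                      config.ipsc_bottleneck,
                                      config.growth_factor, pseed)
    raise ValueError(f"unknown arm {arm!r}")


def simulate_imsc_arm(ipsc_states: Sequence[sim.PopulationState],
                      config: PipelineConfig) -> list[sim.PopulationState]:
    """Differentiation bottleneck applied to the iPSC arm, then expansion.

    The returned series starts with the pre-bottleneck iPSC state, so the
    abrupt diversity drop caused by recruitment is part of the arm's own
    trajectory.
    """
    split = ipsc_states[config.imsc_split_passage]
    recruited = sim.simulate_differentiation_bottleneck(
        split, config.imsc_recruited, stage_seed(config.seed, "recruit:iMSC"))
    return [split] + sim.simulate_passaging(
        recruited, config.imsc_passages, config.msc_bottleneck,
        config.growth_factor, stage_seed(config.seed, "passage:iMSC"))


def sequence_and_count(state: sim.PopulationState, meta: SampleMeta,
                       config: PipelineConfig, seed: int
                       ) -> tuple[cl.AbundanceTable, ex.ExtractionStats]:
    """Sequence one population state and recover its clone table."""
    reads, _ = sim.generate_amplicon_reads(
        state, DEFAULT_TAGS, config.read_count, config.seq_error_rate, seed)
    records = [ex.ReadRecord(r.id, r.sequence) for r in reads]
    calls, stats = ex.process_reads(records, DEFAULT_TAGS)
    table = cl.count_clones([c for c in calls if c.assigned], meta)
    if config.collapse:
        table = cl.collapse_errors(table)
    return table, stats


def arm_report(arm: str, states: Sequence[sim.PopulationState],
               config: PipelineConfig) -> dict:
    """Extraction + diversity across the sampled passages of one arm."""
    cell_type = {"MSC": "MSC", "iPSC": "iPSC", "iMSC": "iMSC"}[arm]
    tables = []
    for i, st in enumerate(states):
        meta = SampleMeta("donor_sim", cell_type, passage=i)
        table, _ = sequence_and_count(
            st, meta, config, stage_seed(config.seed, f"seq:{arm}:{i}"))
        tables.append(table)
    div = cl.diversity_frame(tables)
    traj = cl.trajectory(tables)
    h0, h_end = float(div.shannon_H.iloc[0]), float(div.shannon_H.iloc[-1])
    return {
        "tables": tables,
        "diversity": div,
        "trajectory": traj,
        "initial_H": h0,
        "final_H": h_end,
        "decline_pct": 100.0 * (h0 - h_end) / h0 if h0 > 0 else 0.0,
        "max_one_passage_drop": float((-div.shannon_H.diff()).max()),
        "final_top3_share": float(div.top3_share.iloc[-1]),
    }


def methylation_report(early_state: sim.PopulationState,
                       late_state: sim.PopulationState,
                       founders: Sequence[sim.Founder],
                       config: PipelineConfig, label: str) -> meth.DominanceReport:
    patterns = sim.assign_founder_patterns(
        founders, config.n_cpgs, stage_seed(config.seed, f"meth-pat:{label}"))
    early_reads = sim.simulate_methylation_reads(
        early_state, config.n_cpgs, patterns, config.flip_rate,
        config.meth_reads, stage_seed(config.seed, f"meth-early:{label}"),
        amplicon="CASR")
    late_reads = sim.simulate_methylation_reads(
        late_state, config.n_cpgs, patterns, config.flip_rate,
        config.meth_reads, stage_seed(config.seed, f"meth-late:{label}"),
        amplicon="CASR")
    early = meth.tabulate_patterns(early_reads)
    late = meth.tabulate_patterns(late_reads)
    return meth.pattern_dominance(early, late)


def run_demo(config: PipelineConfig, out_dir) -> dict:
    """Run the three-arm synthetic demonstration; returns the summary dict.

    Fully determined by ``config`` (including its seed): rerunning with the
    same config yields byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    msc_states = simulate_arm("MSC", config)
    ipsc_states = simulate_arm("iPSC", config)
    imsc_states = simulate_imsc_arm(ipsc_states, config)

    reports = {}
    for arm, states in (("MSC", msc_states), ("iPSC", ipsc_states),
                        ("iMSC", imsc_states)):
        log.info("demo arm %s: %d passages", arm, len(states) - 1)
        rep = arm_report(arm, states, config)
        rep["trajectory"].to_csv(out / f"trajectory_{arm}.tsv", sep="\t",
                                 index=False)
        rep["diversity"].to_csv(out / f"diversity_{arm}.tsv", sep="\t",
                                index=False)
        reports[arm] = rep

    # limiting dilution on the simulated clonogenic frequency
    design = sim.simulate_dilution_assay(
        config.dilution_true_f, seed=stage_seed(config.seed, "dilution"))
    design.to_csv(out / "dilution_design.tsv", sep="\t", index=False)
    est = dil.fit_frequency(dil.DilutionDesign.from_frame(design))
    (out / "dilution_estimate.json").write_text(est.to_json())
    mono = dil.select_monoclonal_doses(est, design.dose.tolist())
    pd.DataFrame([(m.dose, m.p_single, m.passes_filter) for m in mono],
                 columns=["dose", "p_single", "passes_filter"]).to_csv(
        out / "monoclonality.tsv", sep="\t", index=False)

    # methylation pattern dominance: iMSC bottleneck arm vs neutral iPSC control
    ipsc_founders = list(ipsc_states[0].abundances)
    dom_imsc = methylation_report(ipsc_states[config.imsc_split_passage],
                                  imsc_states[-1], ipsc_founders, config, "iMSC")
    dom_ctrl = methylation_report(ipsc_states[config.imsc_split_passage],
                                  ipsc_states[-1], ipsc_founders, config, "ctrl")

    summary = {
        "seed": config.seed,
        "arms": {
            arm: {k: rep[k] for k in ("initial_H", "final_H", "decline_pct",
                                      "max_one_passage_drop",
                                      "final_top3_share")}
            for arm, rep in reports.items()
        },
        "dilution": {"true_f": config.dilution_true_f, "f_hat": est.f_hat,
                     "ci_low": est.ci_low, "ci_high": est.ci_high},
        "methylation": {
            "imsc_dominant": dom_imsc.dominant,
            "imsc_top_late_share": dom_imsc.top_patterns_late[0][1],
            "control_dominant": dom_ctrl.dominant,
            "control_top_late_share": dom_ctrl.top_patterns_late[0][1],
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    (out / "config.txt").write_text(config.to_text())
    return summary


# ---------------------------------------------------------------------------
# single-stage runners (file interface used by the CLI)

def stage_simulate(out_dir, config: PipelineConfig) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    states = simulate_arm("MSC", config)
    sim.trajectory_frame(states).to_csv(out / "truth_trajectory.tsv", sep="\t",
                                        index=False)
    reads, truth = sim.generate_amplicon_reads(
        states[-1], DEFAULT_TAGS, config.read_count, config.seq_error_rate,
        stage_seed(config.seed, "seq:simulate"))
    sim.write_fastq(reads, out / "reads.fastq")
    sim.write_truth_table(truth, out / "truth.tsv")
    return {"reads": str(out / "reads.fastq"), "n_reads": len(reads),
            "truth": str(out / "truth.tsv"),
            "trajectory": str(out / "truth_trajectory.tsv")}


def stage_extract(fastq, out_calls, out_stats=None, fastq2=None, tags_path=None,
                  error_rate: float = 0.2, tag_mismatch: int = 2) -> dict:
    tags = load_tags(tags_path) if tags_path else DEFAULT_TAGS
    log.info("extract: %s (md5 %s)", fastq, _file_md5(fastq))
    calls, stats = ex.process_fastq(fastq, tags, path2=fastq2,
                                    max_error_rate=error_rate,
                                    max_mismatch=tag_mismatch)
    ex.calls_frame(calls).to_csv(out_calls, sep="\t", index=False)
    if out_stats:
        Path(out_stats).write_text(stats.to_json() + "\n")
    log.info("extract: %d reads, %d assigned", stats.total_reads, stats.assigned)
    return {"calls": str(out_calls), **dataclasses.asdict(stats)}


def stage_clones(calls_path, out_abundance, donor="NA", cell_type="MSC",
                 passage=0, collapse: bool = True) -> dict:
    df = pd.read_csv(calls_path, sep="\t")
    calls = [ex.BarcodeCall(str(r.read_id), str(r.color), str(r.umi),
                            int(r.tag_mismatches), int(r.trim_edits))
             for r in df.itertuples()]
    meta = SampleMeta(donor, cell_type, int(passage))
    table = cl.count_clones([c for c in calls if c.assigned], meta)
    if collapse:
        table = cl.collapse_errors(table)
    table.to_frame().to_csv(out_abundance, sep="\t", index=False)
    return {"abundance": str(out_abundance), "richness": table.richness,
            "total_reads": table.total}


def stage_diversity(sample_sheet, out_dir, top_k: int = 3,
                    collapse: bool = True) -> dict:
    """Sample sheet TSV: sample_id, donor, cell_type, passage, file (calls TSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sheet = pd.read_csv(sample_sheet, sep="\t")
    tables: dict[tuple, list] = {}
    for r in sheet.itertuples():
        df = pd.read_csv(r.file, sep="\t")
        calls = [ex.BarcodeCall(str(x.read_id), str(x.color), str(x.umi),
                                int(x.tag_mismatches), int(x.trim_edits))
                 for x in df.itertuples()]
        meta = SampleMeta(str(r.donor), str(r.cell_type), int(r.passage))
        t = cl.count_clones([c for c in calls if c.assigned], meta)
        if collapse:
            t = cl.collapse_errors(t)
        tables.setdefault((meta.donor, meta.cell_type), []).append(t)
    outputs = {}
    for (donor, cell_type), ts in tables.items():
        ts.sort(key=lambda t: t.sample.passage)
        label = f"{donor}_{cell_type}"
        cl.diversity_frame(ts, top_k).to_csv(out / f"diversity_{label}.tsv",
                                             sep="\t", index=False)
        cl.trajectory(ts).to_csv(out / f"trajectory_{label}.tsv", sep="\t",
                                 index=False)
        outputs[label] = str(out / f"diversity_{label}.tsv")
    return outputs


def stage_dilution(design_path, out_dir, wells_path=None,
                   monoclonal_only: bool = False, threshold: float = 0.5) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = dil.DilutionDesign.from_frame(pd.read_csv(design_path, sep="\t"))
    est = dil.fit_frequency(design)
    (out / "estimate.json").write_text(est.to_json() + "\n")
    mono = dil.select_monoclonal_doses(est, [g.dose for g in design.groups],
                                       threshold)
    pd.DataFrame([(m.dose, m.p_single, m.passes_filter) for m in mono],
                 columns=["dose", "p_single", "passes_filter"]).to_csv(
        out / "monoclonality.tsv", sep="\t", index=False)
    result = {"f_hat": est.f_hat, "ci_low": est.ci_low, "ci_high": est.ci_high,
              "converged": est.converged}
    if wells_path:
        wells_df = pd.read_csv(wells_path, sep="\t")
        wells = [dil.score_well(
            str(r.well_id),
            None if pd.isna(r.adipo_fraction) else float(r.adipo_fraction),
            None if pd.isna(r.osteo_absorbance) else float(r.osteo_absorbance),
            float(r.dose)) for r in wells_df.itertuples()]
        allowed = ([m.dose for m in mono if m.passes_filter]
                   if monoclonal_only else None)
        summary = dil.summarize_clonal_potential(wells, allowed)
        summary.to_csv(out / "differentiation_summary.tsv", sep="\t", index=False)
        result["differentiation_summary"] = str(out / "differentiation_summary.tsv")
    return result


def stage_methylation(reads_path, out_dir, compare: Optional[str] = None) -> dict:
    """Reads TSV: read_id, sample_id, amplicon, pattern.  ``compare`` is
    ``early_sample_id:late_sample_id``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = pd.read_csv(reads_path, sep="\t",
                     dtype={"pattern": str, "sample_id": str})
    result: dict = {"patterns": {}}
    tables: dict[tuple, meth.PatternTable] = {}
    for (sample_id, amplicon), grp in df.groupby(["sample_id", "amplicon"]):
        reads = [meth.MethylationRead(str(r.read_id), str(amplicon),
                                      str(r.pattern)) for r in grp.itertuples()]
        t = meth.tabulate_patterns(reads)
        tables[(sample_id, amplicon)] = t
        path = out / f"patterns_{sample_id}_{amplicon}.tsv"
        t.to_frame().to_csv(path, sep="\t", index=False)
        betas = meth.mean_methylation(t)
        pd.DataFrame({"cpg": np.arange(1, len(betas) + 1), "beta": betas}).to_csv(
            out / f"betas_{sample_id}_{amplicon}.tsv", sep="\t", index=False)
        result["patterns"][f"{sample_id}:{amplicon}"] = str(path)
    if compare:
        early_id, late_id = compare.split(":")
        dominance = {}
        for amplicon in df.amplicon.unique():
            key_e, key_l = (early_id, amplicon), (late_id, amplicon)
            if key_e in tables and key_l in tables:
                rep = meth.pattern_dominance(tables[key_e], tables[key_l])
                dominance[str(amplicon)] = {
                    "dominant": rep.dominant,
                    "top_late_share": rep.top_patterns_late[0][1],
                    "change": rep.change,
                    "shannon_early": rep.shannon_early,
                    "shannon_late": rep.shannon_late,
                }
        (out / "dominance.json").write_text(json.dumps(dominance, indent=2) + "\n")
        result["dominance"] = dominance
    return result


STAGES = {
    "simulate": stage_simulate,
    "extract": stage_extract,
    "clones": stage_clones,
    "diversity": stage_diversity,
    "dilution": stage_dilution,
    "methylation": stage_methylation,
    "demo": run_demo,
}


def run_stage(stage: str, **kwargs):
    """Dispatch a named pipeline stage; unknown names raise KeyError."""
    if stage not in STAGES:
        raise KeyError(f"unknown stage {stage!r}; have {sorted(STAGES)}")
    return STAGES[stage](**kwargs)
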