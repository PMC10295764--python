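"""End-to-end study orchestration.

A *study* simulates one transcriptome (shared baseline expression and planted
fold changes), realizes it as several experimental *arms* — each arm is an
independent sequencing experiment with its own count noise, optionally with
its mutant replicates pooled into a single library before "sequencing" —
calls DEGs in every arm under every requested criterion, and scores
concordance: pairwise overlap between arms per criterion, and
identification/accuracy of each arm's calls against (i) the planted truth
and (ii) the intersection of the individually sequenced arms' significant
genes (the replicate-anchored reference a real study would use, where truth
is unknowable).

Arm count noise uses seeds derived from the master seed by fixed offsets, so
arms are independent but the whole study is reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from . import __version__ as _version
from .concordance import (GeneSet, MultiwayOverlap, accuracy_fraction,
                          fold_enrichment, harmonize_ids,
                          identification_fraction, multiway_overlap,
                          pairwise_overlap, read_gene_list, read_id_mapping,
                          write_gene_list)
from .criteria import (CriterionSpec, DEGCallResult, call_by_fdr,
                       call_criterion, parse_criterion)
from .expression import ExpressionMatrix, group_summary, normalize_cpm
from .simdata import (MUT, WT, CountMatrix, SimulationConfig, draw_gene_params,
                      pool_replicates, simulate_experiment,
                      write_count_matrix)

__all__ = [
    "ArmDesign",
    "StudyDesign",
    "StudyReport",
    "run_simulation_study",
    "compare_gene_lists",
    "read_config",
    "sim_config_from_dict",
    "study_design_from_dict",
]

#: fixed per-arm seed stride (a prime, to keep arm streams apart from any
#: seed a user is likely to reuse verbatim)
ARM_SEED_STRIDE = 7919


# ---------------------------------------------------------------------------
# flat key-value config files
# ---------------------------------------------------------------------------

def read_config(path) -> dict[str, str]:
    """Parse a flat ``key = value`` config file ('#' starts a comment)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', "
                                 f"got {raw.rstrip()!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            out[key] = value
    return out


_SIM_FIELDS = {f.name: f.type for f in dataclasses.fields(SimulationConfig)}


def sim_config_from_dict(d: dict[str, str],
                         **overrides) -> SimulationConfig:
    """Build a SimulationConfig from string key-values (unknown simulation
    keys are ignored so one file can hold simulation + study keys)."""
    kwargs = {}
    for name in _SIM_FIELDS:
        if name in d:
            raw = d[name]
            if name == "pooling_mode":
                kwargs[name] = raw
            elif name in ("baseline_log_mean", "baseline_log_sd", "dispersion",
                          "frac_up", "frac_down", "fc_low", "fc_high"):
                kwargs[name] = float(raw)
            else:
                kwargs[name] = int(raw)
    kwargs.update(overrides)
    cfg = SimulationConfig(**kwargs)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArmDesign:
    """One sequencing experiment within a study.

    ``pooled`` arms mix all mutant replicate RNA into one pooled library
    before sequencing (the wild-type side is always sequenced individually,
    so SD-based criteria remain available).
    """

    name: str
    replicates_wt: int
    replicates_mut: int
    pooled: bool = False


@dataclass(frozen=True)
class StudyDesign:
    arms: tuple[ArmDesign, ...]
    criteria: tuple[str, ...]
    background_size: int | None = None
    seed: int = 1

    def validate(self) -> None:
        if not self.arms:
            raise ValueError("StudyDesign needs at least one arm")
        names = [a.name for a in self.arms]
        if len(set(names)) != len(names):
            raise ValueError("StudyDesign arm names must be distinct")
        if not self.criteria:
            raise ValueError("StudyDesign needs at least one criterion")
        for token in self.criteria:
            parse_criterion(token)  # raises on unknown token
        for arm in self.arms:
            if arm.replicates_wt < 1 or arm.replicates_mut < 1:
                raise ValueError(f"arm {arm.name!r} needs >= 1 replicate per "
                                 "genotype")


def _parse_arm_token(token: str) -> ArmDesign:
    parts = token.split(":")
    if len(parts) != 4:
        raise ValueError(
            f"bad arm token {token!r}; expected name:reps_wt:reps_mut:pooled "
            "(e.g. indiv6:6:6:0 or pooled6:6:6:1)")
    name, wt, mut, pooled = parts
    return ArmDesign(name, int(wt), int(mut), bool(int(pooled)))


def study_design_from_dict(d: dict[str, str], **overrides) -> StudyDesign:
    """Build a StudyDesign from flat config keys ``arms``, ``criteria``,
    ``background_size``, ``seed``.

    ``arms`` is a comma-separated list of ``name:reps_wt:reps_mut:pooled``
    tokens; ``criteria`` a comma-separated list of criterion tokens.
    """
    kwargs: dict = {}
    if "arms" in d:
        kwargs["arms"] = tuple(_parse_arm_token(t.strip())
                               for t in d["arms"].split(",") if t.strip())
    if "criteria" in d:
        kwargs["criteria"] = tuple(t.strip() for t in d["criteria"].split(",")
                                   if t.strip())
    if "background_size" in d:
        kwargs["background_size"] = int(d["background_size"])
    if "seed" in d:
        kwargs["seed"] = int(d["seed"])
    kwargs.update(overrides)
    design = StudyDesign(**kwargs)
    design.validate()
    return design


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclass
class StudyReport:
    """Machine-readable study outcome. Every percentage is stored alongside
    the integer counts it was computed from, so it can be re-derived."""

    data: dict

    def to_json(self, path=None) -> str:
        text = json.dumps(self.data, indent=2, sort_keys=True,
                          allow_nan=False, default=_jsonable)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def validate(self) -> None:
        """Recompute every stored percentage from its stored counts."""
        for token, block in self.data["criteria"].items():
            for pair in block["pairwise"].values():
                if "percent_overlap" in pair:
                    expect = (100.0 * pair["n_intersection"]
                              / min(pair["n_a"], pair["n_b"]))
                    if abs(pair["percent_overlap"] - expect) > 1e-9:
                        raise ValueError(f"{token}: stored percent_overlap "
                                         "does not recompute from counts")
            for arm in block["arms"].values():
                for key in ("vs_truth_up", "vs_fdr_intersection"):
                    m = arm.get(key)
                    if not m:
                        continue
                    if m.get("identification_pct") is not None:
                        expect = (100.0 * m["n_intersection"]
                                  / m["n_reference"])
                        if abs(m["identification_pct"] - expect) > 1e-9:
                            raise ValueError(
                                f"{token}: identification_pct does not "
                                "recompute from counts")
                    if m.get("accuracy_pct") is not None:
                        expect = (100.0 * m["n_intersection"]
                                  / m["n_candidate"])
                        if abs(m["accuracy_pct"] - expect) > 1e-9:
                            raise ValueError(
                                f"{token}: accuracy_pct does not recompute "
                                "from counts")


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _score_against(candidate: set[str],
                   reference: set[str] | None) -> dict | None:
    """Counts + identification/accuracy of a called set vs a reference set.

    Percentages whose denominator is empty are reported as None rather than
    invented (an empty reference makes identification undefined, an empty
    candidate makes accuracy undefined).
    """
    if reference is None:
        return None
    inter = len(candidate & reference)
    return {
        "n_candidate": len(candidate),
        "n_reference": len(reference),
        "n_intersection": inter,
        "identification_pct":
            100.0 * inter / len(reference) if reference else None,
        "accuracy_pct":
            100.0 * inter / len(candidate) if candidate else None,
    }


# ---------------------------------------------------------------------------
# study execution
# ---------------------------------------------------------------------------

def _arm_matrix(arm: ArmDesign, config: SimulationConfig, arm_seed: int,
                gene_params) -> tuple[CountMatrix, ExpressionMatrix]:
    """Simulate one arm and return its raw counts and analysis CPM matrix."""
    cfg = dataclasses.replace(config,
                              replicates_wt=arm.replicates_wt,
                              replicates_mut=arm.replicates_mut,
                              seed=arm_seed)
    cm, _ = simulate_experiment(cfg, gene_params=gene_params)
    if not arm.pooled:
        return cm, normalize_cpm(cm)
    # pool every mutant replicate into one library, then analyze wild-type
    # individual columns + the single pooled mutant column
    mut_cols = cm.samples_of(MUT)
    pooled = pool_replicates(cm, mut_cols, cfg.pooled_library_size,
                             mode=cfg.pooling_mode, seed=arm_seed + 1)
    wt_cols = cm.samples_of(WT)
    analysis = CountMatrix(cm.counts[wt_cols], cm.sample_meta.loc[wt_cols])
    analysis = analysis.with_sample(f"{MUT}_pooled", pooled.to_numpy(),
                                    genotype=MUT, pooled=True)
    return cm, normalize_cpm(analysis)


def run_simulation_study(config: SimulationConfig, design: StudyDesign,
                         out_dir=None) -> StudyReport:
    """Run a full simulated design evaluation; optionally write all
    intermediate files (per-arm counts/metadata/truth, per-criterion gene
    lists and score tables, report.json) under ``out_dir``."""
    config.validate()
    design.validate()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # shared biology from the master seed; per-arm seeds only steer noise
    gene_params = draw_gene_params(
        dataclasses.replace(config, seed=design.seed))
    truth = gene_params.truth
    truth_up = truth.up_genes

    arms_em: dict[str, ExpressionMatrix] = {}
    for i, arm in enumerate(design.arms):
        arm_seed = design.seed + ARM_SEED_STRIDE * (i + 1)
        cm, em = _arm_matrix(arm, config, arm_seed, gene_params)
        arms_em[arm.name] = em
        if out is not None:
            write_count_matrix(cm, out / f"{arm.name}_counts.tsv",
                               out / f"{arm.name}_samples.tsv")
    if out is not None:
        truth.write_tsv(out / "truth.tsv")

    # replicate-anchored reference: genes significant in every individually
    # sequenced arm (requires >= 2 such arms, like the 735-gene construction)
    fdr_alpha = next((parse_criterion(t).alpha for t in design.criteria
                      if parse_criterion(t).kind == "fdr"), 0.05)
    indiv_arms = [a for a in design.arms if not a.pooled]
    fdr_ref: set[str] | None = None
    if len(indiv_arms) >= 2:
        per_arm = [call_by_fdr(arms_em[a.name], fdr_alpha).called_genes
                   for a in indiv_arms]
        fdr_ref = set.intersection(*per_arm)

    criteria_block: dict[str, dict] = {}
    for token in design.criteria:
        spec = parse_criterion(token)
        calls: dict[str, DEGCallResult | None] = {}
        for arm in design.arms:
            em = arms_em[arm.name]
            if spec.kind == "fdr" and arm.pooled:
                calls[arm.name] = None  # no replicate variance to test
                continue
            calls[arm.name] = call_criterion(spec, matrix=em)
            if out is not None:
                safe = token.replace(":", "_").replace(",", "_").replace("+", "_")
                calls[arm.name].write(
                    list_path=out / f"{arm.name}_{safe}_genes.txt",
                    table_path=out / f"{arm.name}_{safe}_scores.tsv")

        arm_block: dict[str, dict] = {}
        for arm in design.arms:
            res = calls[arm.name]
            if res is None:
                arm_block[arm.name] = {
                    "n_called": None,
                    "note": "criterion not applicable to a pooled arm "
                            "(no replicate variance)",
                    "vs_truth_up": None, "vs_fdr_intersection": None}
                continue
            called = res.called_genes
            arm_block[arm.name] = {
                "n_called": len(called),
                "vs_truth_up": _score_against(called, truth_up),
                "vs_fdr_intersection": _score_against(called, fdr_ref),
            }

        pair_block: dict[str, dict] = {}
        arm_names = [a.name for a in design.arms]
        for i in range(len(arm_names)):
            for j in range(i + 1, len(arm_names)):
                na, nb = arm_names[i], arm_names[j]
                key = f"{na}|{nb}"
                ra, rb = calls[na], calls[nb]
                if ra is None or rb is None:
                    pair_block[key] = {"note": "criterion not applicable to "
                                               "one of the arms"}
                    continue
                sa = GeneSet(na, frozenset(ra.called_genes), "sim")
                sb = GeneSet(nb, frozenset(rb.called_genes), "sim")
                if not sa.ids or not sb.ids:
                    pair_block[key] = {
                        "n_a": len(sa.ids), "n_b": len(sb.ids),
                        "note": "percent overlap undefined for an empty set"}
                    continue
                if design.background_size is not None:
                    ov = fold_enrichment(sa, sb, design.background_size)
                else:
                    ov = pairwise_overlap(sa, sb)
                pair_block[key] = ov.to_dict()

        criteria_block[token] = {"arms": arm_block, "pairwise": pair_block}

    report = StudyReport({
        "provenance": {
            "package": "pooldeg",
            "version": _version,
            "seed": design.seed,
            "config": {f.name: getattr(config, f.name)
                       for f in dataclasses.fields(config)},
            "design": {
                "arms": [dataclasses.asdict(a) for a in design.arms],
                "criteria": list(design.criteria),
                "background_size": design.background_size,
            },
        },
        "reference_sets": {
            "truth_up": {"n": len(truth_up)},
            "truth_down": {"n": len(truth.down_genes)},
            "fdr_intersection": None if fdr_ref is None else
                {"n": len(fdr_ref), "alpha": fdr_alpha,
                 "arms": [a.name for a in indiv_arms]},
        },
        "criteria": criteria_block,
    })
    report.validate()
    if out is not None:
        report.to_json(out / "report.json")
        _write_summary_tsv(report, out / "summary.tsv")
    return report


def _write_summary_tsv(report: StudyReport, path) -> None:
    """Human-readable flat summary; every number also lives in report.json."""
    rows = ["criterion\tarm\tn_called\tident_vs_truth_pct\tacc_vs_truth_pct"
            "\tident_vs_fdr_ref_pct\tacc_vs_fdr_ref_pct"]
    for token, block in report.data["criteria"].items():
        for arm, a in block["arms"].items():
            def fmt(metric, key):
                if not metric or metric.get(key) is None:
                    return "NA"
                return f"{metric[key]:.1f}"
            rows.append("\t".join([
                token, arm,
                "NA" if a["n_called"] is None else str(a["n_called"]),
                fmt(a["vs_truth_up"], "identification_pct"),
                fmt(a["vs_truth_up"], "accuracy_pct"),
                fmt(a["vs_fdr_intersection"], "identification_pct"),
                fmt(a["vs_fdr_intersection"], "accuracy_pct"),
            ]))
    Path(path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# list-vs-list comparison
# ---------------------------------------------------------------------------

def compare_gene_lists(list_paths, mapping_path=None, background_size=None,
                       namespace: str = "user") -> dict:
    """Compare 2+ plain-text gene lists: pairwise overlaps (with enrichment
    when a background size is given) and, for 2-4 lists, the full membership
    partition. An optional mapping table harmonizes all lists first; dropped
    ids are reported per list."""
    paths = list(list_paths)
    if len(paths) < 2:
        raise ValueError("compare_gene_lists needs at least two list files")
    sets = [read_gene_list(p, namespace=namespace) for p in paths]
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):  # disambiguate identical stems
        sets = [GeneSet(f"{s.label}_{i + 1}", s.ids, s.namespace)
                for i, s in enumerate(sets)]

    report: dict = {"lists": {s.label: {"n": len(s)} for s in sets}}
    if mapping_path is not None:
        mapping = read_id_mapping(mapping_path)
        harmonized = []
        unmapped_block = {}
        for s in sets:
            h, unmapped = harmonize_ids(s, mapping)
            harmonized.append(h)
            unmapped_block[s.label] = {"n_unmapped": len(unmapped),
                                       "unmapped_ids": unmapped}
        sets = harmonized
        report["harmonization"] = unmapped_block
        report["lists"] = {s.label: {"n": len(s)} for s in sets}

    pairwise = {}
    for a, b in combinations(sets, 2):
        key = f"{a.label}|{b.label}"
        if background_size is not None:
            pairwise[key] = fold_enrichment(a, b, background_size).to_dict()
        else:
            pairwise[key] = pairwise_overlap(a, b).to_dict()
    report["pairwise"] = pairwise

    if 2 <= len(sets) <= 4:
        report["multiway"] = multiway_overlap(sets).to_dict()
    return report
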