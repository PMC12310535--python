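"""Umbrella pipeline: simulate -> kinship -> uniparental -> ROH/Ne -> clan
statistics, with a YAML run configuration and a single JSON report.

Every stage is also callable on its own, reading the previous stage's
on-disk outputs, so the numbered analysis drivers and the command line can
run any slice of the pipeline.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clanstats import (compare_intra_inter, endogamy_report, mantel_burial,
                        pair_groups, test_lineage_association)
from .community import (SimConfig, pseudo_haploidize, sample_genotypes,
                        simulate_community)
from .formats import (mt_sequences_from_mutations, write_eigenstrat,
                      write_mt_fasta, write_tsv)
from .genmap import GeneticMapSpec
from .kinship import all_pairwise_p0, ibd_summarize, kin_classify, read_classify
from .rohne import InbreedingFilter, bin_roh, estimate_ne_from_bins
from .uniparental import simpson


class ConfigError(ValueError):
    pass


@dataclass
class KinshipConfig:
    window_bp: int = 1_000_000
    min_overlap: int = 20
    min_ibd_cM: float = 12.0
    error_spread: float = 1.5


@dataclass
class RohConfig:
    exclude_threshold_cM: float = 40.0
    long_cM: float = 20.0


@dataclass
class ClanstatsConfig:
    n_perm: int = 9999


@dataclass
class RunConfig:
    seed: int = 0
    map: str | list = "human"
    sim: SimConfig = field(default_factory=SimConfig)
    kinship: KinshipConfig = field(default_factory=KinshipConfig)
    roh: RohConfig = field(default_factory=RohConfig)
    clanstats: ClanstatsConfig = field(default_factory=ClanstatsConfig)

    def gmap(self) -> GeneticMapSpec:
        if self.map == "human":
            return GeneticMapSpec.human_autosomes()
        if self.map == "toy":
            return GeneticMapSpec.toy()
        return GeneticMapSpec.from_rows(self.map)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw or {})
        kwargs = {}
        sections = {"sim": SimConfig, "kinship": KinshipConfig,
                    "roh": RohConfig, "clanstats": ClanstatsConfig}
        for key, section_cls in sections.items():
            sub = dict(raw.pop(key, {}) or {})
            known = {f.name for f in fields(section_cls)}
            unknown = set(sub) - known
            if unknown:
                raise ConfigError(f"unknown keys in '{key}': {sorted(unknown)}")
            kwargs[key] = section_cls(**sub)
        for key in ("seed", "map"):
            if key in raw:
                kwargs[key] = raw.pop(key)
        if raw:
            raise ConfigError(f"unknown top-level keys: {sorted(raw)}")
        cfg = cls(**kwargs)
        cfg.sim.seed = int(cfg.seed)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        payload = {"seed": self.seed, "map": self.map, "sim": asdict(self.sim),
                   "kinship": asdict(self.kinship), "roh": asdict(self.roh),
                   "clanstats": asdict(self.clanstats)}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, fingerprint: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed on input {fingerprint}: {cause}")
        self.stage = stage


def _ibd_cumulative_from_truth(truth_ibd: pd.DataFrame, min_len_cM: float):
    """Per-pair cumulative IBD (cM) from a segment table, IBD1+IBD2."""
    out = {}
    if len(truth_ibd) == 0:
        return out
    lens = truth_ibd["end_cM"] - truth_ibd["start_cM"]
    keep = lens >= min_len_cM
    sub = truth_ibd[keep].assign(length=lens[keep])
    for (a, b), g in sub.groupby(["id1", "id2"]):
        out[(a, b)] = float(g["length"].sum())
    return out


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full pipeline and write per-stage TSVs plus report.json.

    The report is deterministic for a fixed (config, seed): it embeds the
    seed, config hash and package version and no timestamps.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gmap = config.gmap()
    report = {"version": __version__, "seed": int(config.seed),
              "config_hash": config.digest()}

    # --- simulate -----------------------------------------------------------
    try:
        community, truth = simulate_community(config.sim, gmap)
        rng = np.random.default_rng(np.random.SeedSequence(
            [int(config.seed), 1]).generate_state(1)[0])
        geno = sample_genotypes(community, config.sim.n_sites, rng)
        matrix = pseudo_haploidize(geno, config.sim.missing_rate,
                                   config.sim.error_rate, rng)
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", config.digest(), exc) from exc
    roster = community.roster()
    write_tsv(outdir / "roster.tsv", roster)
    write_tsv(outdir / "pairs.tsv", truth.pairs)
    write_tsv(outdir / "ibd.tsv", truth.ibd)
    write_tsv(outdir / "roh.tsv", truth.roh)
    write_eigenstrat(outdir / "community", matrix, roster)
    write_mt_fasta(outdir / "mt.fasta",
                   mt_sequences_from_mutations(community.mt_mutations))
    report["simulate"] = {
        "n_individuals": len(community.individuals),
        "n_external_founders": len(community.externals),
        "n_sites": len(matrix.sites),
        "burial_rule": config.sim.burial_rule,
    }

    # --- kinship ------------------------------------------------------------
    try:
        from .kinship import build_window_grid
        grid = build_window_grid(matrix.sites, config.kinship.window_bp)
        mismatches = all_pairwise_p0(matrix, grid,
                                     min_overlap=config.kinship.min_overlap)
        classed, baseline = read_classify(mismatches)
        kin = [kin_classify(m, baseline,
                            error_spread=config.kinship.error_spread)
               for m in mismatches if not m.insufficient]
        ibd_cum = _ibd_cumulative_from_truth(truth.ibd, config.kinship.min_ibd_cM)
    except Exception as exc:  # noqa: BLE001
        raise StageError("kinship", config.digest(), exc) from exc
    p0_df = pd.DataFrame([{
        "id1": c.id1, "id2": c.id2, "mean_P0": c.mean_p0,
        "normalized_P0": c.normalized_p0, "class": c.degree_class}
        for c in classed])
    write_tsv(outdir / "pairs_p0.tsv", p0_df)
    kin_df = pd.DataFrame([{
        "id1": k.id1, "id2": k.id2, "best_model": k.best_model,
        "log_lr_vs_unrelated": k.log_lr_vs_unrelated, "reliable": k.reliable}
        for k in kin])
    write_tsv(outdir / "kin_models.tsv", kin_df)
    ibd_df = pd.DataFrame([{"id1": a, "id2": b, "cumulative_cM": v,
                            "over_100cM": v > 100.0}
                           for (a, b), v in sorted(ibd_cum.items())])
    write_tsv(outdir / "ibd_summary.tsv", ibd_df)
    report["kinship"] = {
        "baseline_P0": baseline,
        "n_pairs": len(classed),
        "class_counts": p0_df["class"].value_counts().to_dict(),
    }

    # --- uniparental --------------------------------------------------------
    try:
        cemeteries = sorted(roster["cemetery"].unique())
        mt_sdi, y_sdi = {}, {}
        for cem in cemeteries:
            sub = roster[roster["cemetery"] == cem]
            mt_counts = sub["mt_lineage"].value_counts().to_list()
            mt_sdi[cem] = simpson(mt_counts, "plain").value
            males = sub[sub["sex"] == "M"]
            y_counts = males["y_lineage"].value_counts().to_list()
            y_sdi[cem] = (simpson(y_counts, "unbiased").value
                          if len(males) >= 2 else float("nan"))
    except Exception as exc:  # noqa: BLE001
        raise StageError("uniparental", config.digest(), exc) from exc
    report["uniparental"] = {"mt_sdi": mt_sdi, "y_sdi": y_sdi}

    # --- roh / Ne -----------------------------------------------------------
    try:
        filt = InbreedingFilter(long_cM=config.roh.long_cM,
                                threshold_cM=config.roh.exclude_threshold_cM)
        bins = bin_roh(truth.roh, inbreeding_filter=filt)
        ne = estimate_ne_from_bins(bins, gmap)
    except Exception as exc:  # noqa: BLE001
        raise StageError("roh", config.digest(), exc) from exc
    report["roh"] = {
        "n_individuals": len(bins.individuals),
        "n_retained": len(bins.retained),
        "n_consanguineous": int(bins.consanguineous.sum()),
        "ne_mle": ne.ne_mle, "ne_ci_low": ne.ci_low, "ne_ci_high": ne.ci_high,
        "upper_unbounded": ne.upper_unbounded,
    }

    # --- clanstats ----------------------------------------------------------
    try:
        table = roster
        groups = pair_groups(table)
        assoc = test_lineage_association(
            table, n_perm=config.clanstats.n_perm, seed=int(config.seed) + 11)
        comp = compare_intra_inter(
            table, ibd_cum, n_perm=config.clanstats.n_perm,
            seed=int(config.seed) + 12)
        mantels = {}
        for cem in cemeteries:
            sub = table[table["cemetery"] == cem].reset_index(drop=True)
            if len(sub) < 4:
                continue
            n = len(sub)
            gd = np.ones((n, n)) - np.eye(n)
            total = gmap.total_cM
            for i in range(n):
                for j in range(i + 1, n):
                    key = (sub["id"][i], sub["id"][j])
                    v = ibd_cum.get(key, ibd_cum.get(key[::-1], 0.0))
                    gd[i, j] = gd[j, i] = 1.0 - v / total
            res = mantel_burial(sub, gd, n_perm=config.clanstats.n_perm,
                                seed=int(config.seed) + 13)
            mantels[cem] = {"r": res.r, "p": res.p_value,
                            "degenerate": res.degenerate}
        all_pairs = [(a, b) for i, a in enumerate(roster["id"])
                     for b in roster["id"][i + 1:]]
        summaries = [ibd_summarize([(0.0, ibd_cum.get((a, b), 0.0))],
                                   min_len_cM=0.0, pair=(a, b))
                     for a, b in all_pairs]
        endo = endogamy_report(summaries, bins)
    except Exception as exc:  # noqa: BLE001
        raise StageError("clanstats", config.digest(), exc) from exc

    write_tsv(outdir / "pairs_groups.tsv", groups.pairs)
    mt_vals = [v for v in mt_sdi.values() if v == v]
    y_vals = [v for v in y_sdi.values() if v == v]
    matrilineal = bool(assoc.p_value < 0.01 and mt_vals and y_vals
                       and np.mean(mt_vals) < np.mean(y_vals))
    report["clanstats"] = {
        "pair_counts": {"intra": groups.intra_counts, "inter": groups.n_inter},
        "association_p": assoc.p_value,
        "welch_t": comp.t_statistic, "welch_p": comp.t_p_value,
        "permutation_p": comp.permutation_p,
        "mean_intra_cM": comp.mean_intra, "mean_inter_cM": comp.mean_inter,
        "mantel": mantels,
        "endogamy": asdict(endo),
        "burial_organization_call": ("matrilineal-consistent" if matrilineal
                                     else "not-matrilineal-consistent"),
    }

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
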