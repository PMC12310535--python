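#!/usr/bin/env python
"""Cemetery-level social structure: matriline-cemetery association,
intra- versus inter-cemetery IBD, burial-distance versus genetic-distance
independence, and the endogamy summary; ends with the burial-organization
call."""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, run_config  # noqa: E402

from clankin.clanstats import (compare_intra_inter, endogamy_report,
                               mantel_burial, pair_groups,
                               test_lineage_association)
from clankin.formats import read_segments_tsv, write_tsv
from clankin.rohne import bin_roh
from clankin.uniparental import simpson


class _Cum:
    def __init__(self, v):
        self.cumulative_cM = v


def main():
    cfg = run_config()
    gmap = cfg.gmap()
    src = RESULTS / "community"
    out = RESULTS / "clanstats"
    roster = pd.read_csv(src / "roster.tsv", sep="\t")
    ibd_summary = pd.read_csv(RESULTS / "kinship" / "ibd_summary.tsv", sep="\t")
    ibd = {(r.id1, r.id2): r.cumulative_cM
           for r in ibd_summary.itertuples(index=False)}

    groups = pair_groups(roster)
    write_tsv(out / "pairs_groups.tsv", groups.pairs)
    n_perm = cfg.clanstats.n_perm
    assoc = test_lineage_association(roster, n_perm=n_perm, seed=cfg.seed + 11)
    comp = compare_intra_inter(roster, ibd, n_perm=n_perm, seed=cfg.seed + 12)

    mantels = {}
    for cem, sub in roster.groupby("cemetery"):
        sub = sub.reset_index(drop=True)
        if len(sub) < 4:
            continue
        n = len(sub)
        gd = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                key = (sub["id"][i], sub["id"][j])
                v = ibd.get(key, ibd.get(key[::-1], 0.0))
                gd[i, j] = gd[j, i] = 1.0 - v / gmap.total_cM
        res = mantel_burial(sub, gd, n_perm=n_perm, seed=cfg.seed + 13)
        mantels[cem] = {"r": round(res.r, 4), "p": res.p_value}

    ids = list(roster["id"])
    cums = [_Cum(ibd.get((a, b), ibd.get((b, a), 0.0)))
            for i, a in enumerate(ids) for b in ids[i + 1:]]
    endo = endogamy_report(cums, bin_roh(read_segments_tsv(src / "roh.tsv")))

    mt_sdi, y_sdi = [], []
    for _, sub in roster.groupby("cemetery"):
        mt_sdi.append(simpson(sub["mt_lineage"].value_counts().to_list(),
                              "plain").value)
        males = sub[sub["sex"] == "M"]
        if len(males) >= 2:
            y_sdi.append(simpson(males["y_lineage"].value_counts().to_list(),
                                 "unbiased").value)
    matrilineal = (assoc.p_value < 0.01 and mt_sdi and y_sdi
                   and np.mean(mt_sdi) < np.mean(y_sdi))

    report = {
        "pair_counts": {"intra": groups.intra_counts, "inter": groups.n_inter},
        "association": {"observed": assoc.observed, "n": assoc.n,
                        "p": assoc.p_value, "n_perm": n_perm},
        "intra_vs_inter": {"mean_intra_cM": round(comp.mean_intra, 1),
                           "mean_inter_cM": round(comp.mean_inter, 1),
                           "welch_t": round(comp.t_statistic, 2),
                           "welch_p": comp.t_p_value,
                           "permutation_p": comp.permutation_p,
                           "note": comp.note},
        "mantel_within_cemetery": mantels,
        "endogamy": {"frac_pairs_over_100cM": round(
                         endo.frac_pairs_over_100cM, 4),
                     "median_cumulative_cM": round(
                         endo.median_cumulative_cM, 1),
                     "n_consanguineous": endo.n_consanguineous},
        "burial_organization_call": ("matrilineal-consistent" if matrilineal
                                     else "not-matrilineal-consistent"),
        "seed": int(cfg.seed),
    }
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "clanstats.json", "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")

    print(f"matriline-cemetery association: {assoc.observed}/{assoc.n} on the "
          f"modal matriline, permutation p = {assoc.p_value:.4g}")
    print(f"intra vs inter cumulative IBD: {comp.mean_intra:.0f} vs "
          f"{comp.mean_inter:.0f} cM (Welch t = {comp.t_statistic:.1f}, "
          f"permutation p = {comp.permutation_p:.4g})")
    for cem, m in mantels.items():
        print(f"Mantel within {cem}: r = {m['r']:+.3f}, p = {m['p']:.3g} "
              "(burial position does not track genetic distance)")
    print(f"pairs sharing > 100 cM: {endo.frac_pairs_over_100cM:.1%}; "
          f"median cumulative IBD {endo.median_cumulative_cM:.0f} cM")
    print(f"burial-organization call: {report['burial_organization_call']}")
    print(f"wrote clanstats.json, pairs_groups.tsv -> {out}")


if __name__ == "__main__":
    main()
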