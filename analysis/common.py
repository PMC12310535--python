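"""Shared configuration for the numbered analysis drivers.

The headline scenario: two matrilineal clans buried by matriclan, strong
community endogamy with external husbands, pseudo-haploid genotypes with
heavy missingness on a genome-scale map.
"""

from pathlib import Path

from clankin.pipeline import RunConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"

CONFIG = {
    "seed": 1,
    "map": "human",
    "sim": {
        "n_clans": 2, "founders_per_clan": 5, "generations": 4,
        "endogamy_prob": 0.8, "burial_rule": "matriclan",
        "offspring_mean": 2.4, "mt_mut_prob": 0.005,
        "n_sites": 60_000, "missing_rate": 0.5, "error_rate": 0.005,
    },
    "kinship": {"window_bp": 4_000_000, "min_overlap": 15},
    "clanstats": {"n_perm": 4999},
}


def run_config() -> RunConfig:
    return RunConfig.from_dict({k: (dict(v) if isinstance(v, dict) else v)
                                for k, v in CONFIG.items()})
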