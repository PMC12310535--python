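import numpy as np
import pytest

from clankin.community import (Community, Individual, SimConfig, gene_drop,
                               simulate_community)
from clankin.genmap import GeneticMapSpec


@pytest.fixture(scope="session")
def toy_map():
    return GeneticMapSpec.toy()


@pytest.fixture(scope="session")
def small_community(toy_map):
    """A moderately endogamous two-clan community on the toy map."""
    cfg = SimConfig(seed=11, founders_per_clan=4, generations=3,
                    endogamy_prob=0.7, offspring_mean=2.4, n_sites=4000,
                    missing_rate=0.3, error_rate=0.005)
    return simulate_community(cfg, toy_map)


def build_pedigree(rows, gmap, seed=0):
    """Hand-built community from (id, sex, mother, father, generation) rows;
    founders are rows with no parents.  Gene-drops immediately."""
    inds = []
    for iid, sex, mother, father, gen in rows:
        inds.append(Individual(
            id=iid, sex=sex, mother_id=mother, father_id=father,
            generation=gen, matriline="A", patriline="P",
            mt_lineage="A", y_lineage="Y" if sex == "M" else None,
            cemetery="A"))
    com = Community(config=SimConfig(seed=seed), gmap=gmap,
                    individuals=inds, externals=[])
    gene_drop(com, np.random.default_rng(seed))
    return com
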