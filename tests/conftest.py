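import numpy as np
import pandas as pd
import pytest

from eggnest.simulate import simulate_continuous, simulate_tree
from eggnest.trees import Phylogeny


@pytest.fixture(scope="session")
def three_tip_tree() -> Phylogeny:
    return Phylogeny.from_newick("((a:1.0,b:1.0):1.0,c:2.0);")


@pytest.fixture(scope="session")
def yule50() -> Phylogeny:
    return simulate_tree(50, seed=101)


@pytest.fixture(scope="session")
def bm_tips_50(yule50) -> pd.Series:
    y, _ = simulate_continuous(yule50, seed=202, lambda_signal=1.0,
                               sigma2=0.25, root=4.0)
    return y


@pytest.fixture(scope="session")
def quartet_tree() -> Phylogeny:
    return Phylogeny.from_newick("((a:0.3,b:0.5):0.4,(c:0.2,d:0.6):0.3);")
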