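import pandas as pd
import pytest

from c4origins import packaged_data
from c4origins.io_formats import read_newick


@pytest.fixture(scope="session")
def nyctagineae_tree():
    return read_newick(str(packaged_data("nyctagineae_tree.nwk")))


@pytest.fixture(scope="session")
def nyctagineae_states():
    df = pd.read_csv(packaged_data("nyctagineae_states.tsv"), sep="\t")
    return {str(r["taxon"]): (1 if str(r["pathway"]) == "C4" else 0) for _, r in df.iterrows()}


@pytest.fixture(scope="session")
def genus_ranges():
    return pd.read_csv(packaged_data("genus_isotope_ranges.tsv"), sep="\t")


@pytest.fixture(scope="session")
def gas_exchange_summary():
    df = pd.read_csv(packaged_data("gas_exchange_summary.tsv"), sep="\t")
    return df.set_index("parameter")
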