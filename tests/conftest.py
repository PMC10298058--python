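from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from trnamod.chem import default_registry
from trnamod.modseq import ModifiedResidue, ModifiedSequence

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

DATA_DIR = Path(__file__).parent / "data"


def random_sequences():
    """Hypothesis strategy over small modified oligonucleotides."""
    residue = st.one_of(
        st.sampled_from("ACGU").map(ModifiedResidue),
        st.sampled_from(["Ψ", "I"]).map(
            lambda m: ModifiedResidue("U" if m == "Ψ" else "A", m)
        ),
        st.sampled_from(["m^1^G", "m^5^C", "m^1^A"]).map(
            lambda m: ModifiedResidue({"m^1^G": "G", "m^5^C": "C", "m^1^A": "A"}[m], m)
        ),
    )
    return st.builds(
        ModifiedSequence,
        st.lists(residue, min_size=1, max_size=12).map(tuple),
        st.sampled_from(["OH", "p"]),
        st.sampled_from(["OH", "p", ">p"]),
    )


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def fragment_fixture_rows():
    """Curated fragment observations: (fragment, printed_mz, z, table, row, consistent)."""
    rows = []
    lines = (DATA_DIR / "reference_fragments.tsv").read_text(encoding="utf-8").splitlines()
    header = lines[0].split("\t")
    for line in lines[1:]:
        if not line.strip():
            continue
        rec = dict(zip(header, line.split("\t")))
        rows.append(
            (
                rec["fragment"],
                float(rec["printed_mz"]),
                int(rec["z"]),
                rec["table"],
                rec["row"],
                rec["consistent"] == "1",
            )
        )
    return rows
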