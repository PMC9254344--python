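import pandas as pd
import pytest

from cffrag import (
    AnnotationParams,
    GenomeModel,
    PopulationConfig,
    annotate_elements,
    build_genome,
    simulate_population,
)

#: seed used for the shared default-configuration simulation
DEFAULT_SIM_SEED = 11


@pytest.fixture(scope="session")
def toy_genome() -> GenomeModel:
    return GenomeModel((("chr1", 60_000), ("chr2", 40_000), ("chrM", 5_000)))


@pytest.fixture(scope="session")
def toy_params() -> AnnotationParams:
    return AnnotationParams(
        n_genes=6, exons_per_gene=3, exon_length=100, intron_length=400
    )


@pytest.fixture(scope="session")
def toy_annotation(toy_genome, toy_params):
    return annotate_elements(toy_genome, toy_params, seed=2)


@pytest.fixture(scope="session")
def default_genome() -> GenomeModel:
    return build_genome()


@pytest.fixture(scope="session")
def default_annotation(default_genome):
    return annotate_elements(default_genome, seed=1)


@pytest.fixture(scope="session")
def default_sim(default_genome, default_annotation) -> pd.DataFrame:
    """One shared default-configuration simulation (n = 50,000)."""
    return simulate_population(
        default_genome, default_annotation, PopulationConfig(), seed=DEFAULT_SIM_SEED
    )


@pytest.fixture(scope="session")
def uniform_config() -> PopulationConfig:
    """Uniform-placement null: every enrichment multiplier at 1."""
    return PopulationConfig(element_weights={"uscf": {}, "mncf": {}}, size_curves={})


@pytest.fixture(scope="session")
def uniform_sim(default_genome, default_annotation, uniform_config) -> pd.DataFrame:
    return simulate_population(default_genome, default_annotation, uniform_config, seed=21)


def make_fragments(rows) -> pd.DataFrame:
    """Build a schema-complete fragment table from (contig, start, end) dicts."""
    defaults = dict(
        strand="+",
        state="ss",
        nicks="",
        umi="ACGTACGT",
        population="uscf",
        treatment_history="",
    )
    records = []
    for row in rows:
        rec = {**defaults, **row}
        rec["length"] = rec["end"] - rec["start"]
        rec.setdefault("duplex_length", rec["length"])
        records.append(rec)
    cols = [
        "contig", "start", "end", "length", "duplex_length", "strand",
        "state", "nicks", "umi", "population", "treatment_history",
    ]
    if not records:
        from cffrag.fragments import empty_fragments

        return empty_fragments()
    df = pd.DataFrame(records)
    return df[cols]


def fragments_of_lengths(lengths, contig="chrA", umi_prefix="U") -> pd.DataFrame:
    rows = [
        {"contig": contig, "start": 1000 + 500 * i, "end": 1000 + 500 * i + int(L),
         "umi": f"{umi_prefix}{i:07d}"}
        for i, L in enumerate(lengths)
    ]
    return make_fragments(rows)
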