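import pytest

from mapbridge.linkage_io import LinkageMap, MapMarker
from mapbridge.mapping import FilterMode, builtin_test_mapper, filter_alignments
from mapbridge.simdata import SimConfig, simulate


def make_map(species, rows):
    """rows: (lg, cm, marker_id, sequence)"""
    return LinkageMap(
        species,
        [MapMarker(species, lg, cm, mid, seq) for lg, cm, mid, seq in rows],
    )


@pytest.fixture
def tiny_map():
    return make_map(
        "spx",
        [
            ("LG1", 0.0, "m1", "ACGTACGTACGT"),
            ("LG1", 5.0, "m2", "TTTTACGTCCCC"),
            ("LG2", 1.5, "m3", "GGGGACGTAAAA"),
        ],
    )


#: study conditions for the end-to-end recovery runs: 5 ancestral
#: chromosomes, WGD, a non-duplicated outgroup, 2 fusions, 1 fission and
#: one inversion spanning >= 8 sampled markers
RECOVERY_CONFIG = SimConfig(
    seed=11,
    n_ancestral_chromosomes=5,
    branch_events={
        "sp_a,sp_b,sp_c": [("fusion", "1.1", "2.1")],
        "sp_b,sp_c": [("fusion", "3.1", "4.2")],
        "sp_c": [("fission", "1.1", "2.1")],
        "sp_b": [("inversion", "5.1", 0.3, 0.7)],
    },
)


@pytest.fixture(scope="session")
def recovery_sim(tmp_path_factory):
    """Noise-free simulation plus filtered alignments for every tip."""
    out = tmp_path_factory.mktemp("sim")
    res = simulate(RECOVERY_CONFIG, out_dir=out)
    genome = out / "genome.fasta"
    aln = {sp: builtin_test_mapper(res.maps[sp], genome) for sp in res.maps}
    kept = {}
    for sp in res.maps:
        mode = (
            FilterMode.homeolog(min_mapq=0)
            if sp == RECOVERY_CONFIG.outgroup
            else FilterMode.standard()
        )
        kept[sp], _ = filter_alignments(aln[sp], mode)
    return {"result": res, "genome": genome, "alignments": aln, "kept": kept, "dir": out}
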