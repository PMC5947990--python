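import pytest

from epitag.annotation_io import load_annotation, load_genome
from epitag.fixtures import FixtureSpec, PlantedOfftarget, generate_fixtures


@pytest.fixture(scope="session")
def fixture_set(tmp_path_factory):
    """Standard synthetic fixture: 4 transcripts (alternating strands) with
    planted 3'UTR sites at cut distances {12,40} / {5,28}, plus decoy
    off-target loci at Hamming distances 1-4 (NGG) and 2 (NAG) for the first
    planted guide."""
    spec = FixtureSpec(
        seed=1,
        n_transcripts=4,
        offtargets=[
            PlantedOfftarget(0, 0, 1, "NGG"),
            PlantedOfftarget(0, 0, 2, "NGG"),
            PlantedOfftarget(0, 0, 3, "NGG"),
            PlantedOfftarget(0, 0, 4, "NGG"),
            PlantedOfftarget(0, 0, 2, "NAG"),
        ],
    )
    fs = generate_fixtures(spec, tmp_path_factory.mktemp("fix"))
    return fs


@pytest.fixture(scope="session")
def fixture_paths(fixture_set, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixfiles")
    return fixture_set.write(out)


@pytest.fixture(scope="session")
def genome(fixture_paths):
    return load_genome(fixture_paths["fasta"])


@pytest.fixture(scope="session")
def catalog(fixture_paths, genome):
    return load_annotation(fixture_paths["gtf"], genome)


def grid_fixture(tmp_path, n, seed=11, distances=None):
    """n-transcript fixture set, loaded: (FixtureSet, GenomeSequence, catalog)."""
    spec = FixtureSpec(
        seed=seed, n_transcripts=n, cut_distances=distances or [[5, 28]]
    )
    fs = generate_fixtures(spec)
    paths = fs.write(tmp_path)
    g = load_genome(paths["fasta"])
    cat = load_annotation(paths["gtf"], g)
    return fs, g, cat


@pytest.fixture(scope="session")
def designs(tmp_path_factory):
    """~200 end-to-end designs (50 transcripts x up to 2 guides x 2 tags)."""
    from epitag.donor_design import get_tag
    from epitag.pipeline import design_for_target

    tmp = tmp_path_factory.mktemp("ki")
    _, g, cat = grid_fixture(tmp, 50, seed=17, distances=[[12, 40], [5, 28]])
    out = []
    for tag_name in ("V5", "HA"):
        tag = get_tag(tag_name)
        for tid in sorted(cat):
            bundle = design_for_target(tid, tag, g, cat)
            for gd in bundle.guides:
                out.append((bundle.region, tag, gd))
    return out


def make_toy_files(tmp_path, fasta_records, gtf_lines):
    fa = tmp_path / "toy.fa"
    fa.write_text("".join(f">{n}\n{s}\n" for n, s in fasta_records))
    gtf = tmp_path / "toy.gtf"
    gtf.write_text("\n".join(gtf_lines) + "\n")
    return fa, gtf
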