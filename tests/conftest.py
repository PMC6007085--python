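import pytest

from megbids import FixtureSpec, generate_dataset, scan_tree


@pytest.fixture(scope="session")
def valid_tree_path(tmp_path_factory):
    """A canonical valid fixture tree (2 subjects, empty-room, anatomy)."""
    out = tmp_path_factory.mktemp("fixture") / "ds"
    generate_dataset(FixtureSpec(seed=7, n_sub=2), out)
    return out


@pytest.fixture()
def valid_tree(valid_tree_path):
    return scan_tree(valid_tree_path)


@pytest.fixture(scope="session")
def expected_files(tmp_path_factory):
    """(tree path, expected relative file list) for inventory comparisons."""
    out = tmp_path_factory.mktemp("fixture_exp") / "ds"
    _tree, expected = generate_dataset(FixtureSpec(seed=7, n_sub=3, n_ses=2, n_run=2), out)
    return out, expected
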