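import dendropy
import numpy as np
import pytest

from supermatrixqc.align import AlignedOrthogroup, Record


def make_orthogroup(locus_id, rows, delimiter="|"):
    """rows: list of (sequence_id, residues); taxon = id before delimiter."""
    return AlignedOrthogroup(
        locus_id,
        [Record(sid.split(delimiter, 1)[0], sid, res) for sid, res in rows],
    )


def parse_tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True)


def random_bl_tree(rng, n_leaves, prefix="t", multifurcate_prob=0.0):
    """Random topology with exponential branch lengths, optionally with
    random polytomies; returns a dendropy tree."""
    labels = [f"{prefix}{i}" for i in range(1, n_leaves + 1)]
    nodes = [f"{lbl}:{rng.exponential(0.3):.6f}" for lbl in labels]
    while len(nodes) > 3:
        k = 3 if (multifurcate_prob and rng.random() < multifurcate_prob
                  and len(nodes) > 3) else 2
        picks = sorted(rng.choice(len(nodes), size=k, replace=False), reverse=True)
        group = [nodes.pop(i) for i in picks]
        nodes.append(f"({','.join(group)}):{rng.exponential(0.3):.6f}")
    newick = f"({','.join(nodes)});"
    return parse_tree(newick)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
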