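import numpy as np
import pandas as pd
import pytest

import trophonet as tn


@pytest.fixture(scope="session")
def rules_fixture():
    """Bundled 22-group rule-set toy dataset: rules, counts, taxonomy, metadata."""
    return tn.make_rules_fixture()


@pytest.fixture(scope="session")
def demo_dataset():
    """Small five-guild simulated dataset with planted ground truth."""
    cfg = tn.five_guild_demo_config(
        seed=7, n_individuals_per_group=4, reads_per_individual=3000
    )
    return tn.simulate_dataset(cfg)


@pytest.fixture()
def tiny_counts_tsv(tmp_path):
    df = pd.DataFrame(
        [[5, 0, 2, 7], [1, 3, 0, 0], [0, 8, 4, 2]],
        index=["s1", "s2", "s3"],
        columns=["otuA", "otuB", "otuC", "otuD"],
    )
    path = tmp_path / "counts.tsv"
    df.rename_axis("sample_id").to_csv(path, sep="\t")
    return path, df


def pagerank_dense_oracle(nodes, edges, damping):
    """Independent PageRank oracle: direct linear solve of the fixed point
    with uniform dangling redistribution and uniform teleportation."""
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    p = np.zeros((n, n))
    for u, v, w in edges:
        p[idx[v], idx[u]] += w
    out = p.sum(axis=0)
    dangling = out == 0
    p[:, ~dangling] /= out[~dangling]
    m = p.copy()
    m[:, dangling] += 1.0 / n
    r = np.linalg.solve(np.eye(n) - damping * m, np.full(n, (1 - damping) / n))
    return {v: r[idx[v]] for v in nodes}
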