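"""Independent reference implementations used only to check the package.

Each oracle recomputes a quantity by the most transparent route available
(dense linear algebra, exhaustive enumeration, naive resampling) and stays
deliberately separate from the code paths it validates.
"""

import itertools

import numpy as np


def dense_mcl(graph, inflation=1.5, n_iter=200, structure_tol=1e-6):
    """Brute-force Markov clustering: dense matrices, fixed iteration
    count, clusters = connected components of the converged structure."""
    nodes = sorted(graph.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        if u == v:
            continue
        w = float(data.get("weight", 1.0))
        a[idx[u], idx[v]] = a[idx[v], idx[u]] = w
    loops = a.max(axis=0)
    loops[loops == 0.0] = 1.0
    a[np.diag_indices(n)] = loops
    m = a / a.sum(axis=0, keepdims=True)
    for _ in range(n_iter):
        m = m @ m
        m = m**inflation
        m /= m.sum(axis=0, keepdims=True)
    adj = (m > structure_tol) | (m.T > structure_tol)
    seen = np.zeros(n, dtype=bool)
    clusters = set()
    for start in range(n):
        if seen[start]:
            continue
        stack = [start]
        comp = set()
        while stack:
            i = stack.pop()
            if seen[i]:
                continue
            seen[i] = True
            comp.add(nodes[i])
            stack.extend(np.nonzero(adj[i])[0])
        clusters.add(frozenset(comp))
    return clusters


def enumeration_site_loglik(alignment, tree, model):
    """Site log-likelihoods by summing over every assignment of states to
    internal nodes (exponential; fine for <= 5 leaves)."""
    from neogut.synthio import AA_ALPHABET

    idx = {c: i for i, c in enumerate(AA_ALPHABET)}
    nodes = list(tree.postorder_node_iter())
    internals = [nd for nd in nodes if not nd.is_leaf()]
    leaves = [nd for nd in nodes if nd.is_leaf()]
    n_sites = len(next(iter(alignment.values())))
    pmats = {
        nd: model.transition_matrix(nd.edge.length or 0.0)
        for nd in nodes
        if nd.parent_node is not None
    }
    pi = model.frequencies
    out = np.zeros(n_sites)
    for site in range(n_sites):
        leaf_state = {nd: idx[alignment[nd.taxon.label][site]] for nd in leaves}
        total = 0.0
        for assignment in itertools.product(range(20), repeat=len(internals)):
            states = dict(zip(internals, assignment))
            states.update(leaf_state)
            lik = pi[states[tree.seed_node]]
            for nd in nodes:
                if nd.parent_node is None:
                    continue
                lik *= pmats[nd][states[nd.parent_node], states[nd]]
            total += lik
        out[site] = np.log(total)
    return out


def naive_rell_winner_counts(site_ll, n_replicates, seed):
    """Plain RELL bootstrap at scale 1: how often each topology has the
    highest resampled total log-likelihood (ties split evenly)."""
    rng = np.random.default_rng(seed)
    n_topo, n_sites = site_ll.shape
    counts = np.zeros(n_topo)
    for _ in range(n_replicates):
        cols = rng.integers(0, n_sites, size=n_sites)
        totals = site_ll[:, cols].sum(axis=1)
        winners = np.flatnonzero(totals >= totals.max() - 1e-9)
        counts[winners] += 1.0 / len(winners)
    return counts / n_replicates


def all_bipartitions_by_enumeration(tree):
    """Bipartitions via dendropy's own encoding (independent of the
    package's traversal)."""
    import dendropy

    t = dendropy.Tree(tree)
    t.encode_bipartitions()
    labels = sorted(lf.taxon.label for lf in t.leaf_node_iter())
    ref = min(labels)
    out = set()
    for bip in t.bipartition_encoding:
        side = {
            taxon.label
            for taxon in t.taxon_namespace
            if bip.leafset_bitmask & t.taxon_namespace.taxon_bitmask(taxon)
        }
        if ref in side:
            side = set(labels) - side
        if 2 <= len(side) <= len(labels) - 2:
            out.add(frozenset(side))
    return out
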