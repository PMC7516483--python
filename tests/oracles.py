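"""Independent brute-force oracles shared across test modules."""

import networkx as nx


def brute_force_shells(net):
    """Shell index by literal repeated pruning of minimum-degree nodes."""
    g = nx.Graph(net.to_networkx().to_undirected())
    shell = {}
    k = 0
    while g.number_of_nodes():
        while True:
            low = [v for v, d in g.degree() if d <= k]
            if not low:
                break
            for v in low:
                shell[v] = k
                g.remove_node(v)
        k += 1
    return shell
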