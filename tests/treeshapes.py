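"""Enumeration and sampling of unrooted leaf-labeled tree topologies."""

from __future__ import annotations


def enumerate_topologies(labels: list[str]) -> list[str]:
    """All unrooted binary leaf-labeled topologies, as newick strings.

    Stepwise addition: every tree on n leaves arises uniquely by attaching
    the n-th leaf to one of the 2n-5 edges of a tree on n-1 leaves, so the
    counts are 1, 3, 15, 105, 945, ... for n = 3, 4, 5, 6, 7, ...
    """
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")
    trees = [(labels[0], labels[1], labels[2])]

    def edges(tree):
        out = []

        def walk(node, path):
            out.append(path)
            if isinstance(node, tuple):
                for i, child in enumerate(node):
                    walk(child, path + (i,))

        for i, child in enumerate(tree):
            walk(child, (i,))
        return out

    def attach_sub(node, path, leaf):
        if not path:
            return (node, leaf)
        i, rest = path[0], path[1:]
        return tuple(
            attach_sub(c, rest, leaf) if k == i else c for k, c in enumerate(node)
        )

    def attach_top(tree, path, leaf):
        i, rest = path[0], path[1:]
        return tuple(
            attach_sub(c, rest, leaf) if k == i else c for k, c in enumerate(tree)
        )

    for leaf in labels[3:]:
        trees = [attach_top(t, path, leaf) for t in trees for path in edges(t)]

    def to_newick(node):
        if isinstance(node, tuple):
            return "(" + ",".join(to_newick(c) for c in node) + ")"
        return node

    return [to_newick(t) + ";" for t in trees]


def random_topology(labels: list[str], rng) -> str:
    """One random unrooted binary topology by random pairwise joining."""
    nodes = list(labels)
    while len(nodes) > 3:
        a = nodes.pop(rng.randrange(len(nodes)))
        b = nodes.pop(rng.randrange(len(nodes)))
        nodes.append(f"({a},{b})")
    return "(" + ",".join(nodes) + ");"
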