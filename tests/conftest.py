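import pytest

from idbos import AggregatedNetwork


@pytest.fixture
def toy_network() -> AggregatedNetwork:
    """O_AB = 2, O_AC = 1; counts N_A = 3, N_B = 2, N_C = 1, N = 3."""
    return AggregatedNetwork({("A", "B"): 2, ("A", "C"): 1})


#: diverse feasible networks small enough for exhaustive matching
#: enumeration (2N <= 12 stubs): forced matchings, hubs, stars, disjoint
#: edges, triangles and multi-edges.
TINY_NETWORKS = [
    {("A", "B"): 1},
    {("A", "B"): 2},
    {("A", "B"): 1, ("A", "C"): 1},
    {("A", "B"): 2, ("C", "D"): 1},
    {("A", "B"): 1, ("A", "C"): 1, ("C", "D"): 1},
    {("A", "B"): 3, ("A", "C"): 1},
    {("A", "B"): 2, ("A", "C"): 2, ("B", "C"): 1},
    {("A", "B"): 1, ("C", "D"): 1, ("E", "F"): 1},
    {("A", "B"): 2, ("B", "C"): 2, ("C", "D"): 2},
    {("A", "B"): 1, ("A", "C"): 1, ("A", "D"): 1, ("A", "E"): 1, ("A", "F"): 1},
    {("A", "B"): 3, ("C", "D"): 3},
    {("A", "B"): 2, ("A", "C"): 1, ("B", "D"): 1, ("C", "D"): 1, ("E", "F"): 1},
]


@pytest.fixture(params=TINY_NETWORKS, ids=lambda d: "+".join(f"{a}{b}x{o}" for (a, b), o in sorted(d.items())))
def tiny_network(request) -> AggregatedNetwork:
    return AggregatedNetwork(dict(request.param))
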