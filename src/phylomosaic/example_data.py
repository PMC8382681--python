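"""Bundled example dataset statistics.

``DROSOPHILID_MARKER_STATS`` is the published per-marker summary table of a
17-marker, 83-taxon drosophilid supermatrix (14,961 aligned sites after
concatenation): per marker, the occupancy (sequences present out of 83 taxa),
alignment length, percentage of parsimony-informative sites, mean inferred
(patristic) and observed (p-) pairwise distances, the saturation slope, and
the concordance bookkeeping against an 83-taxon reference tree (concordant
nodes out of 80 internal branches, missing nodes, and the concordance
percentage over assessable nodes).

The table is used by the worked examples and the reproduction script as input
data: the package's concordance arithmetic and summary statistics can be
recomputed directly from these printed counts.
"""

from .seqio import MarkerStats

#: Markers with a pre-existing phylogenetic track record (ribosomal,
#: metabolic and mitochondrial genes).
PREEXISTING_MARKERS = ["28S", "Adh", "Amyrel", "COI", "COII", "Gpdh", "Sod", "Xdh"]

#: Developmental-gene markers newly designed for the drosophilid study.
NEW_MARKERS = ["Ddc", "Dll", "eb", "en", "eve", "hh", "Notum", "ptc", "wg"]

#: Total taxa and internal reference branches of the source analysis.
N_TAXA = 83
N_NODES = 80  # = N_TAXA - 3 for a resolved unrooted reference

DROSOPHILID_MARKER_STATS = [
    # marker, n_seq, sites, informative%, inferred, observed, saturation,
    # concordant, missing, concordance%
    MarkerStats("28S", 49, N_TAXA, 848, 18.4, 0.200, 0.189, 0.700, 25, N_NODES, 44, 69.4),
    MarkerStats("Adh", 53, N_TAXA, 724, 54.4, 0.886, 0.331, 0.430, 28, N_NODES, 35, 62.2),
    MarkerStats("Amyrel", 48, N_TAXA, 1475, 53.5, 2.458, 0.545, 0.290, 18, N_NODES, 44, 50.0),
    MarkerStats("COI", 51, N_TAXA, 1438, 33.8, 1.119, 0.666, 0.191, 35, N_NODES, 40, 87.5),
    MarkerStats("COII", 57, N_TAXA, 688, 37.8, 1.004, 0.169, 0.185, 40, N_NODES, 33, 85.1),
    MarkerStats("Gpdh", 26, N_TAXA, 859, 35.0, 0.784, 0.286, 0.400, 9, N_NODES, 64, 56.3),
    MarkerStats("Sod", 22, N_TAXA, 574, 49.3, 1.072, 0.333, 0.373, 4, N_NODES, 68, 33.3),
    MarkerStats("Xdh", 19, N_TAXA, 2088, 42.4, 0.919, 0.314, 0.368, 9, N_NODES, 68, 75.0),
    MarkerStats("Ddc", 52, N_TAXA, 1162, 42.3, 1.003, 0.262, 0.358, 27, N_NODES, 39, 65.9),
    MarkerStats("Dll", 56, N_TAXA, 377, 30.8, 0.629, 0.229, 0.463, 40, N_NODES, 36, 90.9),
    MarkerStats("eb", 67, N_TAXA, 891, 46.7, 1.247, 0.318, 0.380, 32, N_NODES, 21, 54.2),
    MarkerStats("en", 51, N_TAXA, 1119, 51.1, 1.009, 0.307, 0.371, 18, N_NODES, 41, 46.2),
    MarkerStats("eve", 66, N_TAXA, 806, 48.6, 1.083, 0.303, 0.367, 40, N_NODES, 22, 69.0),
    MarkerStats("hh", 63, N_TAXA, 486, 62.6, 1.203, 0.352, 0.400, 29, N_NODES, 27, 54.7),
    MarkerStats("Notum", 51, N_TAXA, 672, 62.6, 1.005, 0.352, 0.417, 18, N_NODES, 45, 51.4),
    MarkerStats("ptc", 60, N_TAXA, 430, 55.8, 1.076, 0.323, 0.413, 42, N_NODES, 29, 82.4),
    MarkerStats("wg", 57, N_TAXA, 324, 51.5, 1.223, 0.321, 0.352, 33, N_NODES, 33, 70.2),
]
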