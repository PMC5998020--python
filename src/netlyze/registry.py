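"""Frozen, versioned registries of measure names.

The ROI registry pairs 12 node-level summaries (mean/median over nodes of
degree, neighbor degree and clustering coefficient, in both weighted and
unweighted modes) with 10 graph-level summaries evaluated in both modes,
for exactly 32 entries.  Structure-only graph measures (component counts,
node count) coincide across modes but keep both slots so the feature
vector has a fixed 32 x 24 layout.

The blob registry fixes the 28-entry descriptor: 4 size, 11 shape,
4 hollowness and 9 network features.
"""

from __future__ import annotations

ROI_REGISTRY_VERSION = "1.0"
BLOB_REGISTRY_VERSION = "1.0"

#: (registry name, node-measure key, statistic) for the 12 node-level entries.
_NODE_LEVEL = [
    ("uwAvgDeg", "uw_degree", "mean"),
    ("uwMedDeg", "uw_degree", "median"),
    ("wAvgDeg", "w_degree", "mean"),
    ("wMedDeg", "w_degree", "median"),
    ("uwAvgNDeg", "uw_ndeg", "mean"),
    ("uwMedNDeg", "uw_ndeg", "median"),
    ("wAvgNDeg", "w_ndeg", "mean"),
    ("wMedNDeg", "w_ndeg", "median"),
    ("uwAvgCC", "uw_cc", "mean"),
    ("uwMedCC", "uw_cc", "median"),
    ("wAvgCC", "w_cc", "mean"),
    ("wMedCC", "w_cc", "median"),
]

#: (registry name, graph-measure key, weighted?) for the 20 graph-level entries.
_GRAPH_LEVEL = [
    ("uwCharPath", "char_path", False),
    ("wCharPath", "char_path", True),
    ("uwGlobalEff", "global_eff", False),
    ("wGlobalEff", "global_eff", True),
    ("uwModularity", "modularity", False),
    ("wModularity", "modularity", True),
    ("uwNModules", "n_modules", False),
    ("wNModules", "n_modules", True),
    ("uwAssort", "assortativity", False),
    ("wAssort", "assortativity", True),
    ("uwDensity", "density", False),
    ("wDensity", "density", True),
    ("uwNComp", "n_components", False),
    ("wNComp", "n_components", True),
    ("uwLargestCompFrac", "largest_comp_frac", False),
    ("wLargestCompFrac", "largest_comp_frac", True),
    ("uwMeanCompSize", "mean_comp_size", False),
    ("wMeanCompSize", "mean_comp_size", True),
    ("uwNodeCount", "node_count", False),
    ("wNodeCount", "node_count", True),
]

ROI_MEASURES: tuple[str, ...] = tuple(
    [name for name, _, _ in _NODE_LEVEL] + [name for name, _, _ in _GRAPH_LEVEL]
)
assert len(ROI_MEASURES) == 32

#: The 28 blob-descriptor feature names, grouped by role.
BLOB_SIZE_FEATURES = ("volume", "x_range", "y_range", "z_range")
BLOB_SHAPE_FEATURES = (
    "sphericity", "fractional_anisotropy", "linearity", "planarity",
    "pca_lambda1", "pca_lambda2", "pca_lambda3",
    "pca_ratio21", "pca_ratio31", "pca_ratio32", "pca_total_var",
)
BLOB_HOLLOWNESS_FEATURES = (
    "dist_centroid_min", "dist_centroid_mean",
    "dist_centroid_max", "dist_centroid_sd",
)
BLOB_NETWORK_FEATURES = (
    "n_nodes", "uw_avg_degree", "w_avg_degree", "uw_avg_cc", "w_avg_cc",
    "char_path", "modularity", "n_modules", "n_components",
)
BLOB_FEATURES: tuple[str, ...] = (
    BLOB_SIZE_FEATURES + BLOB_SHAPE_FEATURES
    + BLOB_HOLLOWNESS_FEATURES + BLOB_NETWORK_FEATURES
)
assert len(BLOB_FEATURES) == 28
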