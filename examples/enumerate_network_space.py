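"""Enumerate the 2-4-ROI connectivity network search space.

Builds the 16-ROI registry, enumerates every unordered 2-4-ROI network,
and applies the occipital-cortex control filters.  The three counts are
the size of the multiple-comparison family and of the two control
subsets; the feature length is the dimensionality of one example
network's classifier input.
"""

import wmconn as w

registry = w.build_registry("connectivity-16")
networks = w.enumerate_networks(registry, sizes={2, 3, 4})
with_oc = w.filter_networks(networks, must_include={"LOC", "ROC"})
oc_no_stc = w.filter_networks(
    networks, must_include={"LOC", "ROC"}, must_exclude={"LSTC", "RSTC"}
)

print(f"candidate networks (2-4 ROIs of 16): {len(networks)}")
print(f"  containing occipital cortex:       {len(with_oc)}")
print(f"  occipital but no sup. temporal:    {len(oc_no_stc)}")

net = w.ROINetwork(members=(registry["LSTC"], registry["LSMG"], registry["RSTC"]))
print(f"feature length of {net.label}: {net.feature_len}")
print(f"fsaverage3 vertices per hemisphere: {w.ico_vertex_count(3)}")
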