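"""Social, per-user dataset recommendations.

A user who owns a private dataset still receives recommendations driven
by it; following a user surfaces their public data; filters restrict
similarity-based items to one comparison route.
"""

from covrec import DatasetRecord, SimilarityEdge, SocialGraph, recommend

records = {
    "priv": DatasetRecord("priv", "e1", "hg19-like", "RNA-seq", "heart",
                          owner="alice", public=False),
    "pub1": DatasetRecord("pub1", "e2", "hg19-like", "RNA-seq", "heart", owner="bob"),
    "pub2": DatasetRecord("pub2", "e3", "hg19-like", "RNA-seq", "cardiomyocyte", owner="bob"),
    "hidden": DatasetRecord("hidden", "e4", "hg19-like", "RNA-seq", "heart",
                            owner="bob", public=False),
}
edges = {
    SimilarityEdge("priv", "pub1", by_primary=True, by_metadata=False),
    SimilarityEdge("priv", "hidden", by_primary=True, by_metadata=True),
    SimilarityEdge("pub1", "pub2", by_primary=False, by_metadata=True),
}

graph = SocialGraph()
for user in ("alice", "bob"):
    graph.add_user(user)
graph.own("alice", "priv")
for d in ("pub1", "pub2", "hidden"):
    graph.own("bob", d)
graph.follow("alice", "bob")

for filter_ in ("all", "primary_only", "metadata_only"):
    recs = recommend(graph, edges, records, "alice", filter_)
    print(f"filter={filter_}:")
    for r in recs:
        src = [s for s, on in (("primary", r.by_primary), ("metadata", r.by_metadata)) if on]
        print(f"  {r.dataset_id}: reasons={sorted(r.reasons)} sources={src or '-'}")
# "hidden" is similar to alice's data but private to bob, so it never
# appears.  "pub1" survives the metadata_only filter through the follow
# route even though its similarity edge is primary-only.
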