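"""Watch the learned representation space separate during training.

Extracts the fused pre-head representations before and after training,
projects them to 2-D with PCA, and measures the distance between the
success and fail class centroids.  Coordinates go to CSV for plotting.
"""

from pathlib import Path

from trialmatch import SiameseMatcher, SyntheticSpec, TrainConfig, generate_coarse, train
from trialmatch.cluster import centroid_distance, export_scatter, extract_fused, reduce_2d
from trialmatch.encoders import EncoderConfig

pairs = generate_coarse(SyntheticSpec(n_pairs=80, pos_fraction=0.3,
                                      separation=1.0, seed=4))
model = SiameseMatcher(
    EncoderConfig("mlp", input_dim=64, projection_dim=64, dropout_rate=0.1, seed=4),
    fusion="concat", loss_kind="wbce",
)

out = Path("scratch_cluster_demo")
out.mkdir(exist_ok=True)
for stage in ("before", "after"):
    rep = extract_fused(model, pairs)
    coords = reduce_2d(rep.matrix, method="pca")
    export_scatter(coords, rep.labels, out / f"{stage}.csv",
                   pair_ids=rep.pair_ids, epoch=rep.epoch)
    dist = centroid_distance(coords, rep.labels)
    print(f"{stage} training (epoch {rep.epoch:>2}): "
          f"class-centroid distance {dist:.3f}")
    if stage == "before":
        train(model, pairs, TrainConfig(seed=4))
# a growing centroid distance means the fused embedding space pulls
# eligible and ineligible pairs into separate clusters as training proceeds
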