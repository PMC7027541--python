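"""DBSCAN cluster analysis of a synthetic SMLM field.

Generates a 12 um^2 field of view with 30 ground-truth Syk clusters
(Gaussian blobs, 10 nm spread) over a uniform background, filters
localizations to photon counts > 500, clusters at eps 25 nm / min_pts
10, and prints the four cluster metrics: detections per cluster, hull
area, clusters per um^2, and within-cluster detection density.
"""

import numpy as np

import vplatelet as vp

spec = vp.FieldSpec(seed=7)  # defaults: 12 um^2, 30 clusters
table, truth = vp.gen_localizations(spec)
print(f"generated {len(table)} detections "
      f"({spec.n_clusters} true clusters + background)")

params = vp.ClusterParams()  # eps 25 nm, min_pts 10, photons > 500
filtered = vp.filter_photons(table, params.photon_threshold)
print(f"photon filter >{params.photon_threshold:.0f}: kept {len(filtered)}")

result = vp.dbscan(filtered, params)
metrics = vp.cluster_metrics(result, roi_area_um2=spec.roi_area_um2)
pc = metrics["per_cluster"]
print(f"found {metrics['n_clusters']} clusters "
      f"({metrics['clusters_per_um2']:.2f} clusters/um^2, "
      f"truth {spec.n_clusters / spec.roi_area_um2:.2f}), "
      f"{metrics['n_noise']} noise points")
print(f"detections/cluster {pc['n_detections'].mean():.1f}, "
      f"hull area {pc['hull_area_nm2'].mean():.0f} nm^2, "
      f"density {np.nanmean(pc['density_per_nm2']):.4f} detections/nm^2")
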