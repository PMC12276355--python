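"""Segment a synthetic multiplex slide into compartments and score proteins.

Generates one 8-channel slide with planted tumor structures, runs the full
spatial chain (channel correction -> k-means masks -> compartment labeling ->
cellularity-corrected scores) and prints where each marker concentrates.
"""

from routescape import imaging as im
from routescape.synthetic import ImageScenario, gen_multiplex_image

scen = ImageScenario(seed=1)
img, truth = gen_multiplex_image(scen)

corrected = im.correct_channels(img, penalty=5.0)
T, V = im.segment_base(corrected, k=5, seed=1)
labels = im.label_compartments((T, V), scen.compartment_params)

areas = im.compartment_areas(labels)
scores = im.compartment_scores(corrected, labels, eps=1.0)

print("relative compartment areas (fractions of the slide):")
print(areas.round(4).to_string())
print()
print("protein scores (mean marker/DAPI ratio per compartment):")
print(scores.scores.round(2).to_string())
print()
top = scores.scores.loc["marker_pv"].idxmax()
print(
    f"the planted perivascular marker scores highest in the {top!r} compartment,"
    "\nreproducing the enrichment readout the spatial scoring is built for."
)
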