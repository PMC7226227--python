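"""Score a synthetic slide end to end.

Renders a slide with 7 planted TMEM doorways plus one distractor of each
kind, trains the pixel classifier from generated annotated fields, and
runs the full pipeline: stain unmixing -> pixel classification -> object
morphometry -> contact cascade -> field ranking.
"""

from tmemdp import synthetic
from tmemdp.evaluation import train_default_model
from tmemdp.scoring import score_slide
from tmemdp.slide_io import CalibrationParams, full_image_roi

spec = synthetic.SlideSpec(seed=42, n_tmem_triads=7)
image, label_mask, truth = synthetic.generate_slide(spec)
model = train_default_model(seed=0)
calib = CalibrationParams(microns_per_pixel=1.0)

result = score_slide(image, full_image_roi(image.shape[:2]), model, calib)

print(f"planted TMEM doorways : {truth.expected_count}")
print(f"TMEM score            : {result.score}")
print(f"risk category         : {result.risk}")
print(f"TA vessels / TA macs  : {result.metrics['ta_vessels']:.0f} / "
      f"{result.metrics['ta_macs']:.0f}")
print(f"interface length (um) : {result.metrics['interface_um']:.0f}")
print("per-tile counts       :",
      {idx: c for idx, c in sorted(result.per_tile_counts.items())})
# The score is the sum of doorway counts over the top-10 ranked fields;
# with 6 fields on this small slide it equals the total recovered count,
# which matches the planted ground truth exactly. A score of 7 falls in
# the intermediate risk band (cutoffs: low <= 6 < intermediate <= 23 < high).
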