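"""Run the directory workflow on a simulated multi-plate scan.

A 3x3 composite scan (nine plates on a black scanner mask) is split into
rough crops, each is straightened and fine-cropped to its colony grid, the
grid is validated, and Standard-mode measurements are appended to a log
file. Images land in the stage folders (rough_crops, fine_crops,
measurements_passed, ...error folders) exactly as the pipeline progresses.
"""

import tempfile
from pathlib import Path

from colonygrid import FORMAT_384, RunConfig, run_directory
from colonygrid.synthplate import ScreenSpec, generate_screen

tmp = Path(tempfile.mkdtemp())
spec = ScreenSpec(format=FORMAT_384, arrangement=(3, 3),
                  conditions=("control",), rotation_sd=1.5, seed=4)
generate_screen(spec, tmp)

result = run_directory(tmp, RunConfig(format=FORMAT_384, mode="standard",
                                      layout="multi", arrangement=(3, 3)))

statuses = [v["status"] for v in result["status"].values()]
print(f"layout detected: {result['layout']}")
print(f"plates measured: {statuses.count('measured')}")
print(f"fine-crop errors: {statuses.count('fine_crop_error')}")
print(f"measurement errors: {statuses.count('measurement_error')}")
print(f"log file: {result['log']}")
for d in ("rough_crops", "fine_crops", "measurements_passed"):
    n = len(list((tmp / d).glob("*.png")))
    print(f"  {d}: {n} image(s)")
# Every plate of the composite ends in exactly one terminal folder; the log
# file holds 384 area values per successfully measured plate.
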