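"""Generate a small synthetic strip dataset and inspect its structure.

Creates 24 seeded strip photographs (balanced over the negative class and
the three concentration bins), writes YOLO-format labels and a YAML
manifest, and prints the class balance and one label file.
"""

from collections import Counter

from stripnet.synthetic import generate_dataset, read_labels

manifest = generate_dataset(24, "example_data", seed=42, image_size=160,
                            val_fraction=0.25)

counts = Counter(e["strip_class"] for e in manifest["entries"])
print("strip-class balance (−1 = negative):", dict(sorted(counts.items())))
print("class names:", manifest["class_names"])
print("train/val sizes:", len(manifest["splits"]["train"]),
      len(manifest["splits"]["val"]))

first = manifest["entries"][0]
print(f"\n{first['image']}: condition={first['condition']}, "
      f"concentration={first['concentration']} IU/L")
for box in read_labels("example_data/" + first["label"]):
    print("  label:", box)
# Each line is `class cx cy w h` in normalized YOLO convention; class 0 is
# the C-line, classes 1-3 are T-lines binned by concentration.
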