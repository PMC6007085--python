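"""Metadata inheritance: the description file closer to the data prevails.

A study-wide sidecar at the root sets PowerLineFrequency to 60 Hz; the
run-level sidecar overrides it to 50 Hz and adds DewarPosition.  The
resolution trace shows which file contributed each effective key.
"""
import json
import tempfile
from pathlib import Path

from megbids import resolve, scan_tree

with tempfile.TemporaryDirectory() as tmp:
    root = Path(tmp)
    run_dir = root / "sub-01" / "meg"
    run_dir.mkdir(parents=True)
    (root / "task-rest_meg.json").write_text(json.dumps({"PowerLineFrequency": 60}))
    (run_dir / "sub-01_task-rest_run-01_meg.json").write_text(
        json.dumps({"PowerLineFrequency": 50, "DewarPosition": "upright"})
    )
    (run_dir / "sub-01_task-rest_run-01_meg.fif").write_bytes(b"")

    tree = scan_tree(root)
    target = tree.find("sub-01/meg/sub-01_task-rest_run-01_meg.fif")
    trace = resolve(tree, target, "meg")
    print("effective metadata:", trace.effective)
    for path, depth, keys in trace.applied:
        print(f"  depth {depth}: {path} contributes {keys}")
    # The run-level file wins both keys: 50 Hz, not the root's 60 Hz.
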