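"""Parse and build MEG-BIDS filenames.

A filename is entity key-value pairs in canonical order plus a suffix and
extension.  Parsing is total: invalid names yield a single reason code
instead of an exception.
"""
from megbids import EntitySet, build_name, expected_location, parse_name, try_parse_name

es = parse_name("sub-01_ses-01_task-rest_run-01_meg.fif")
print("entities:", es.as_dict(), "suffix:", es.suffix, "ext:", es.extension)
print("expected directory:", expected_location(es))

# canonical writer: run is zero-padded, entities re-ordered canonically
noise = EntitySet.create({"sub": "01", "task": "noise", "run": "1"}, "meg", "ds")
print("built name:", build_name(noise))

for bad in ["sub-01_run-01_task-rest_meg.fif", "sub-01_task-re!st_meg.fif"]:
    _, reason = try_parse_name(bad)
    print(f"rejected {bad!r}: {reason}")
# bad-order: run may not precede task; bad-label: labels are alphanumeric only.
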