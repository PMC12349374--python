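"""Play a full five-level therapy session with the scripted maze bot.

The bot follows the shortest path through each level's checkpoints; the
collision script injects deliberate wall bumps so the error accounting
has a known ground truth.  One tick is 100 ms of game time.
"""

from oculomaze import run_session, default_levels
from oculomaze.io import sessions_frame
from oculomaze.synthetic import maze_bot

# Three scripted wall bumps per level -> exactly 3 errors per level.
record = run_session(default_levels(),
                     lambda maze: maze_bot(maze, [(2, None), (7, None), (11, None)]),
                     user_id="demo", mode="Bin")

print(sessions_frame([record]).to_string(index=False))
print(f"\nsession total: {record.total_ms} ms, {record.total_errors} errors")
# Time-CHKP columns are the first-entry times of each level's two
# checkpoint zones; the Performance Ratio is total time per collision,
# the session table's efficiency figure (higher = fewer errors per ms).
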