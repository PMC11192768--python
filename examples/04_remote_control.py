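"""Drive a chip over the message bus, exercising all three remote modes.

A virtual chip device and a remote client share an in-process
publish/subscribe bus with MQTT-style topics. The client (1) actuates a
single valve manually, (2) uploads a staining script, and (3) runs it by
name, streaming status messages back.
"""

import liftgate as lg
from liftgate.remote import ChipDevice, MessageBus, RemoteClient

bus = MessageBus()
device = ChipDevice(bus, "chip01")
device.backend.apply_protocol_loads(lg.default_protocol())
client = RemoteClient(bus, "chip01")

# mode 1: manual valve control
status = client.manual_valve_command("open", 3)
print("manual  :", status.payload["detail"])
client.manual_valve_command("close", 3)

# mode 3: upload a new script for future use
status = client.upload_script("stain", lg.reference_staining_script())
print("upload  :", status.payload["detail"])
print("stored  :", client.list_scripts())

# mode 2: run the saved script; the final status is the completion report
final = client.run_saved_script("stain")[-1].payload
print(f"run     : {final['status']} — {final['n_actuations']} actuations, "
      f"{final['total_duration_ms'] / 60000:.1f} min virtual time")
print(f"delivered {device.backend.delivered().volume_nl:.1f} nL to the detector")
# Every command got a status reply with its msg_id: nothing is dropped.
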