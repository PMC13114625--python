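{
 "nodes": [
  "Y",
  "Z",
  "V1",
  "V2",
  "U1",
  "U2"
 ],
 "hidden": [
  "U1",
  "U2"
 ],
 "edges": [
  [
   "Z",
   "Y"
  ],
  [
   "Z",
   "V1"
  ],
  [
   "Z",
   "V2"
  ],
  [
   "U1",
   "V1"
  ],
  [
   "U1",
   "Y"
  ],
  [
   "U2",
   "V2"
  ],
  [
   "U2",
   "Y"
  ]
 ],
 "arcs": []
}
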