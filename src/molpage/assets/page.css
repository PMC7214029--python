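/* molpage default page styling: narrow narrative column beside the
 * viewer viewport; prolinks get the classic dotted-underline cue. */
body {
  font-family: Georgia, "Times New Roman", serif;
  margin: 0 auto;
  max-width: 60rem;
  padding: 1rem;
  line-height: 1.5;
  color: #222222;
}
#molpage-viewport {
  width: 100%;
  height: 28rem;
  border: 1px solid #cccccc;
  background: #fafafa;
  margin: 1rem 0;
}
#molpage-front-image {
  max-width: 100%;
  cursor: pointer;
}
a.prolink {
  color: #00695c;
  text-decoration: none;
  border-bottom: 1px dotted #00695c;
  cursor: pointer;
}
.molpage-switcher {
  margin: 0.5rem 0;
  font-size: 0.9rem;
}
.molpage-switcher label {
  margin-right: 1rem;
}
.molpage-unmappable {
  color: #8a6d3b;
}
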