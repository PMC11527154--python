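// mRNA delivery via lipoplexes -- fully nested transfection variant.
// SYNTHETIC TRANSCRIPTION: the rule structure follows the published
// description of the study (lipoplexes as compartments carrying an
// mRNA load drawn from a normal distribution; clathrin pits; endosomes;
// unpacking both in the cytosol and inside endosomes); the kinetic
// constants below are NON-CANONICAL stand-ins chosen to give plausible
// dynamics, not the study's parameterization.
//
// Initial state: 1 cell and 200 extracellular lipoplexes (201
// compartments).  Extracellular lipoplexes are washed away at t = 1 h
// by a scheduled event (configured at run level, not in this file).

const kP: 0.012 / h;    // pit nucleation around a lipoplex (per clathrin)
const kA: 0.0008 / h;   // additional lipoplex joins a pit
const kI: 0.8 / h;      // endocytosis of a pit (per pit)
const kD: 0.25 / h;     // pit dissociation (releases content)
const kL: 0.003 / h;    // endosomal escape (lysis) releasing content
const dE: 0.20 / h;     // endosome degradation (content destroyed)
const kU: 0.30 / h;     // lipoplex unpacking (cytosol and endosome)
const dM: 0.095 / h;    // mRNA degradation
const kT: 5.0 / h;      // translation initiation per mRNA
const dP: 0.023 / h;    // protein degradation

species Cell();
species L();            // lipoplex (compartment carrying mRNA)
species P();            // clathrin-coated pit (compartment)
species E();            // endosome (compartment)
species Clathrin();
species Ribosome();
species mRNA();
species Protein();

init 1 Cell{ 300 Ribosome }
   + 200 L{ (max(1, norm(350, 110))) mRNA }
   + 40 Clathrin;

// pit formation and growth at the membrane (root scope)
Clathrin:cl + L{?sl} -> P{ L{?sl} } @ kP*#cl;
P{?p} + L{?sl} -> P{ L{?sl} + ?p } @ kA;
P{?p} -> Clathrin + ?p @ kD;

// endocytosis: the pit's full content enters the cell in an endosome
Cell{?c} + P{?p} -> Cell{ E{?p} + ?c } + Clathrin @ kI;

// endosomal escape and degradation
Cell{ E{?e} + ?c } -> Cell{ ?e + ?c } @ kL;
Cell{ E{?e} + ?c } -> Cell{ ?c } @ dE;

// unpacking: in the cytosol and (fully nested) inside the endosome
Cell{ L{?sl} + ?c } -> Cell{ ?sl + ?c } @ kU;
Cell{ E{ L{?sl} + ?e } + ?c } -> Cell{ E{ ?sl + ?e } + ?c } @ kU;

// mRNA degradation in the endosome and in the cytosol
E{ mRNA:m + ?e } -> E{ ?e } @ dM*#m;
Cell{ mRNA:m + ?c } -> Cell{ ?c } @ dM*#m;

// translation and protein turnover
Cell{ mRNA:m + Ribosome:r + ?c } -> Cell{ mRNA + Ribosome + Protein + ?c } @ kT*#m;
Cell{ Protein:pr + ?c } -> Cell{ ?c } @ dP*#pr;

observe Protein: Protein in Cell;
observe mRNAcell: mRNA in Cell;
observe Lipoplexes: L;
observe Pits: P;
observe Endosomes: E;
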