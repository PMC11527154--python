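// Fission yeast: multi-cellular cell-cycle model with mating types.
// SYNTHETIC TRANSCRIPTION: the structure follows the published
// description (cells as dividing compartments; cyclin/cdc2 forming
// MPF in active/inactive/repressed states whose oscillation drives
// the cycle phases; pheromones of the opposite mating type repress
// the cycle; M-type cells secrete the protease Sxa2 which degrades
// P-factor).  Kinetic constants are NON-CANONICAL stand-ins: the
// oscillation and division dynamics are qualitative, not the study's.
//
// 7 species, 20 rules.  Time unit: minutes.

const kSyn:  0.55 / min;    // cyclin synthesis
const dCyc:  0.02 / min;    // free cyclin decay
const kAss:  0.004 / min;   // cyclin + cdc2 association (per pair)
const kAct0: 0.004 / min;   // basal MPF activation
const kAct:  0.5 / min;     // autocatalytic MPF activation
const kInact: 0.02 / min;   // active MPF inactivation
const kDis:  0.15 / min;    // active MPF dissociation (cyclin degraded)
const kG1:   1.0 / min;     // G1 -> SG2 transition (gated on active MPF)
const kSG2:  1.0 / min;     // SG2 -> M transition (gated on active MPF)
const kDiv:  0.6 / min;     // division of M-phase cells (during the MPF spike)
const kGrow: 0.2 / min;     // volume growth steps
const kSec:  1.0 / min;     // pheromone secretion
const kSxa:  0.5 / min;     // Sxa2 secretion by M-type cells
const kRep:  0.004 / min;   // MPF repression by opposite-type pheromone
const kDerep: 0.05 / min;   // spontaneous derepression
const kCut:  0.02 / min;    // Sxa2 cleaves P-factor
const dPh:   0.05 / min;    // pheromone decay
const Kact:  30;            // half saturation, autocatalytic activation
const Kph:   60;            // half saturation, pheromone repression
const Kmpf:  25;            // half saturation, phase gates

species Cell(phase: enum {G1 SG2 M}, type: enum {P M}, vol: real);
species Cyclin();
species Cdc2();
species MPF(state: enum {a i r});
species PhP();              // P-factor pheromone
species PhM();              // M-factor pheromone
species Sxa2();

init 1 Cell(phase="G1", type="P", vol=1.0){ 150 Cdc2 + 20 Cyclin }
   + 1 Cell(phase="G1", type="M", vol=1.0){ 150 Cdc2 + 20 Cyclin };

// --- cell-cycle core (inside each cell) -----------------------------
Cell{?c} -> Cell{ Cyclin + ?c } @ kSyn;
Cyclin:y -> @ dCyc*#y;
Cyclin:y + Cdc2:c -> MPF(state="i") @ kAss*#y*#c;
MPF(state=="i"):mi -> MPF(state="a") @ kAct0*#mi;
MPF(state=="i"):mi + MPF(state=="a"):ma -> MPF(state="a") + MPF(state="a")
    @ kAct*#mi*hill(#ma, Kact, 2);
MPF(state=="a"):ma -> MPF(state="i") @ kInact*#ma;
MPF(state=="a"):ma -> Cdc2 @ kDis*#ma;
MPF(state=="r"):mr -> MPF(state="i") @ kDerep*#mr;

// --- phase progression and growth -----------------------------------
Cell(phase=="G1"){ MPF(state=="a"):ma + ?c } -> Cell(phase="SG2"){ MPF + ?c }
    @ kG1*hill(#ma, Kmpf, 4);
Cell(phase=="SG2"){ MPF(state=="a"):ma + ?c } -> Cell(phase="M"){ MPF + ?c }
    @ kSG2*hill(#ma, Kmpf, 4);
Cell(vol<4.0) -> Cell(vol=Cell.vol+0.01) @ kGrow;

// division: during the mitotic MPF spike the M-phase cell splits;
// the daughter may switch mating type
Cell(phase=="M"){ MPF(state=="a"):ma + ?c1 + ?c2 }
    -> Cell(phase="G1", vol=Cell.vol/2){ MPF + ?c1 }
     + Cell(phase="G1", vol=Cell.vol/2,
            type=if unif(0,1) < 0.43 then "P" else "M"){ ?c2 }
    @ kDiv*hill(#ma, Kmpf, 4);

// --- pheromone communication (extracellular) ------------------------
Cell(type=="P"){?c} -> Cell{?c} + PhP @ kSec;
Cell(type=="M"){?c} -> Cell{?c} + PhM @ kSec;
Cell(type=="M"){?c} -> Cell{?c} + Sxa2 @ kSxa;
Cell(type=="P"){ MPF(state=="i"):mi + ?c } + PhM:f
    -> Cell{ MPF(state="r") + ?c } + PhM @ kRep*#mi*hill(#f, Kph, 2);
Cell(type=="M"){ MPF(state=="i"):mi + ?c } + PhP:f
    -> Cell{ MPF(state="r") + ?c } + PhP @ kRep*#mi*hill(#f, Kph, 2);
Sxa2:s + PhP:p -> Sxa2 @ kCut*#s*#p;
PhP:p -> @ dPh*#p;
PhM:f -> @ dPh*#f;

observe Cells: Cell;
observe MPFa: MPF(state=="a");
observe MPFi: MPF(state=="i");
observe MPFr: MPF(state=="r");
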